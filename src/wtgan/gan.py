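"""Adversarial training for tabular data: Wasserstein critic and
standard-GAN baseline.

The generator maps standard-normal latent points to encoded table rows;
the critic scores rows.  In ``wgan`` mode the critic is an unbounded
scorer trained to widen the real-fake score gap, its weights hard-
clipped after every update to enforce a Lipschitz bound, and both
networks are optimized with RMSprop.  In ``gan`` mode (the tabular-GAN
baseline) the critic is a sigmoid discriminator trained with binary
cross-entropy and Adam, and the generator uses the non-saturating loss.

Each epoch performs ``critic_steps`` critic updates on half-batches of
real and generated rows (real target 1, fake target 0), then one
generator update through the frozen critic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import ColumnCodec, EncodedTable, decode_table
from .io_expression import ExpressionTable
from .nn import MLP, Adam, RMSprop

__all__ = [
    "GanConfig",
    "TrainingHistory",
    "generate_latent_points",
    "make_real_batch",
    "make_fake_batch",
    "critic_loss_wgan",
    "generator_loss_wgan",
    "adversarial_losses_gan",
    "train_wtgan",
    "sample_synthetic",
    "augment_table",
]

_EPS = 1e-7


@dataclass
class GanConfig:
    """Architecture and training hyperparameters.

    ``mode='wgan'`` is the Wasserstein model (RMSprop, weight clipping,
    linear critic output); ``mode='gan'`` is the tabular-GAN baseline
    (Adam, binary cross-entropy, sigmoid discriminator).
    """

    latent_dim: int = 64
    gen_hidden: tuple[int, ...] = (128, 256)
    critic_hidden: tuple[int, ...] = (256, 128)
    epochs: int = 5000
    batch_size: int = 32
    mode: str = "wgan"
    learning_rate: float | None = None  # mode default: 5e-5 wgan / 2e-4 gan
    clip_value: float = 0.01
    critic_steps: int | None = None  # mode default: 5 wgan / 1 gan
    seed: int = 0
    n_synthetic: int = 100

    def __post_init__(self):
        if self.mode not in ("wgan", "gan"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.epochs < 0 or self.latent_dim < 1:
            raise ValueError("epochs must be >= 0 and latent_dim >= 1")
        if self.batch_size % 2 != 0:
            raise ValueError("batch_size must be even (half-batch construction)")
        if self.mode == "wgan" and not self.clip_value > 0:
            raise ValueError("wgan mode requires clip_value > 0")
        if self.learning_rate is None:
            self.learning_rate = 5e-5 if self.mode == "wgan" else 2e-4
        if self.critic_steps is None:
            self.critic_steps = 5 if self.mode == "wgan" else 1

    def to_dict(self) -> dict:
        return {
            "latent_dim": self.latent_dim,
            "gen_hidden": list(self.gen_hidden),
            "critic_hidden": list(self.critic_hidden),
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "mode": self.mode,
            "learning_rate": self.learning_rate,
            "clip_value": self.clip_value,
            "critic_steps": self.critic_steps,
            "seed": self.seed,
            "n_synthetic": self.n_synthetic,
        }


@dataclass
class TrainingHistory:
    generator_loss: list[float] = field(default_factory=list)
    critic_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.generator_loss)

    def record(self, gen_loss: float, critic_loss: float) -> None:
        self.generator_loss.append(float(gen_loss))
        self.critic_loss.append(float(critic_loss))


class TrainingDivergedError(RuntimeError):
    pass


def generate_latent_points(
    latent_dim: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ``n_samples × latent_dim`` standard-normal latent batch."""
    if latent_dim < 1 or n_samples < 1:
        raise ValueError("latent_dim and n_samples must be positive")
    return rng.standard_normal(n_samples * latent_dim).reshape(n_samples, latent_dim)


def make_real_batch(
    encoded: EncodedTable, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample rows without replacement; adversarial target 1 (real)."""
    if n_samples > encoded.n_rows:
        raise ValueError(f"requested {n_samples} rows from a table of {encoded.n_rows}")
    idx = rng.choice(encoded.n_rows, size=n_samples, replace=False)
    return encoded.data[idx], np.ones(n_samples)


def make_fake_batch(
    generator: MLP, latent_dim: int, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate rows from latent noise; adversarial target 0 (fake)."""
    z = generate_latent_points(latent_dim, n_samples, rng)
    batch = generator(z)
    return batch, np.zeros(n_samples)


def critic_loss_wgan(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """-(mean real score - mean fake score): minimizing widens the gap."""
    return float(-(np.mean(real_scores) - np.mean(fake_scores)))


def generator_loss_wgan(fake_scores: np.ndarray) -> float:
    """-mean fake score: the generator pushes critic scores of fakes up."""
    return float(-np.mean(fake_scores))


def _bce(p: np.ndarray, target: float) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def adversarial_losses_gan(
    real_probs: np.ndarray, fake_probs: np.ndarray
) -> tuple[float, float]:
    """Binary cross-entropy losses of the standard GAN.

    Critic: BCE against targets 1 (real) and 0 (fake), averaged.
    Generator: non-saturating BCE of fake probabilities against target 1.
    """
    critic = 0.5 * (_bce(real_probs, 1.0) + _bce(fake_probs, 0.0))
    gen = _bce(fake_probs, 1.0)
    return critic, gen


def build_generator(latent_dim: int, out_width: int, hidden: tuple[int, ...],
                    rng: np.random.Generator) -> MLP:
    return MLP([latent_dim, *hidden, out_width], output="linear", rng=rng)


def build_critic(in_width: int, hidden: tuple[int, ...], mode: str,
                 rng: np.random.Generator) -> MLP:
    output = "linear" if mode == "wgan" else "sigmoid"
    return MLP([in_width, *hidden, 1], output=output, rng=rng)


def _critic_update(critic, opt, x_real: np.ndarray, x_fake: np.ndarray, mode: str) -> float:
    """One critic update on a half-batch of real + half-batch of fake rows.

    The two halves form a single combined loss (the Wasserstein gap, or
    the two-target binary cross-entropy) and one optimizer step.
    """
    x = np.vstack([x_real, x_fake])
    n_r, n_f = x_real.shape[0], x_fake.shape[0]
    s = critic(x).ravel()
    s_real, s_fake = s[:n_r], s[n_r:]
    if mode == "wgan":
        loss = critic_loss_wgan(s_real, s_fake)
        grad = np.concatenate([np.full(n_r, -1.0 / n_r), np.full(n_f, 1.0 / n_f)])
    else:
        loss = 0.5 * (_bce(s_real, 1.0) + _bce(s_fake, 0.0))
        p = np.clip(s, _EPS, 1.0 - _EPS)
        target = np.concatenate([np.ones(n_r), np.zeros(n_f)])
        denom = np.concatenate([np.full(n_r, 2.0 * n_r), np.full(n_f, 2.0 * n_f)])
        grad = (p - target) / (p * (1.0 - p)) / denom
    critic.backward(grad.reshape(-1, 1))
    opt.step()
    return loss


def train_wtgan(
    encoded: EncodedTable,
    config: GanConfig,
    callback=None,
) -> tuple[MLP, TrainingHistory]:
    """Alternating adversarial training on an encoded table.

    Per epoch: ``critic_steps`` critic updates, each on a half-batch of
    real rows (target 1) and a half-batch of generated rows (target 0),
    with weight clipping after every update in wgan mode; then one
    generator update through the frozen critic on a full batch of latent
    points.  ``callback(epoch, critic)`` runs after every critic update.
    Fully reproducible from ``config.seed``.
    """
    if encoded.n_rows == 0:
        raise ValueError("encoded table is empty")
    rng = np.random.default_rng(config.seed)
    width = encoded.width
    generator = build_generator(config.latent_dim, width, tuple(config.gen_hidden), rng)
    critic = build_critic(width, tuple(config.critic_hidden), config.mode, rng)
    history = TrainingHistory()
    if config.epochs == 0:
        return generator, history

    if config.mode == "wgan":
        c_opt = RMSprop(critic, lr=config.learning_rate)
        g_opt = RMSprop(generator, lr=config.learning_rate)
    else:
        c_opt = Adam(critic, lr=config.learning_rate)
        g_opt = Adam(generator, lr=config.learning_rate)

    half = max(1, min(config.batch_size // 2, encoded.n_rows))
    for epoch in range(config.epochs):
        c_loss = 0.0
        for _ in range(config.critic_steps):
            x_real, _ = make_real_batch(encoded, half, rng)
            x_fake, _ = make_fake_batch(generator, config.latent_dim, half, rng)
            c_loss = _critic_update(critic, c_opt, x_real, x_fake, config.mode)
            if config.mode == "wgan":
                critic.clip_weights(config.clip_value)
            if callback is not None:
                callback(epoch, critic)

        # generator update through the frozen critic
        z = generate_latent_points(config.latent_dim, config.batch_size, rng)
        x = generator(z)
        s = critic(x).ravel()
        n = s.shape[0]
        if config.mode == "wgan":
            g_loss = generator_loss_wgan(s)
            grad_s = np.full((n, 1), -1.0 / n)
        else:
            g_loss = _bce(s, 1.0)
            p = np.clip(s, _EPS, 1.0 - _EPS)
            grad_s = ((p - 1.0) / (p * (1.0 - p)) / n).reshape(-1, 1)
        grad_x = critic.backward(grad_s)  # critic weights untouched: no opt.step()
        generator.backward(grad_x)
        g_opt.step()

        if not (np.isfinite(c_loss) and np.isfinite(g_loss)):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        history.record(g_loss, c_loss)
    return generator, history


def augment_table(
    train: ExpressionTable,
    config: GanConfig,
    n_synthetic: int | None = None,
    n_modes: int = 5,
    encoding_method: str = "gmm",
    return_history: bool = False,
):
    """Train one GAN per class on ``train`` and emit labelled synthetic rows.

    Conditioning by class partition gives every synthetic sample an exact
    label and class-conditional expression marginals; a single GAN with a
    jointly generated label column only ties labels to expression after
    far longer training than small tables warrant.  Per-class sample
    counts are proportional to the training class frequencies.  All
    randomness derives from ``config.seed``.
    """
    from . import encoding  # local import to avoid a cycle at module load

    if n_synthetic is None:
        n_synthetic = config.n_synthetic
    if n_synthetic <= 0:
        raise ValueError("n_synthetic must be positive")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training table contains a single class")
    parts: list[ExpressionTable] = []
    histories: dict[int, TrainingHistory] = {}
    for i, cls in enumerate(classes):
        sub = train.subset_samples(np.where(train.labels == cls)[0])
        codecs = encoding.fit_codecs(sub, n_modes=n_modes, seed=config.seed,
                                     method=encoding_method)
        enc = encoding.encode_table(sub, codecs, np.random.default_rng(config.seed))
        cls_config = GanConfig(**{**config.to_dict(), "seed": config.seed + i})
        generator, history = train_wtgan(enc, cls_config)
        histories[int(cls)] = history
        n_cls = int(round(n_synthetic * (train.labels == cls).mean()))
        n_cls = max(n_cls, 1)
        syn = sample_synthetic(
            generator, codecs, n_cls, np.random.default_rng(config.seed + 10 + i)
        )
        syn.labels[:] = cls  # label block is constant within a class partition
        parts.append(syn)
    values = np.vstack([p.values for p in parts])
    labels = np.concatenate([p.labels for p in parts])
    synthetic = ExpressionTable(
        values,
        list(train.gene_ids),
        [f"syn{i}" for i in range(values.shape[0])],
        labels,
        name=f"{config.mode}-synthetic",
    )
    if return_history:
        return synthetic, histories
    return synthetic


def sample_synthetic(
    generator: MLP,
    codecs: list[ColumnCodec],
    n_synthetic: int,
    rng: np.random.Generator,
    name: str = "synthetic",
) -> ExpressionTable:
    """Emit ``n_synthetic`` decoded synthetic samples in the original gene
    space, labels taken from the generated categorical block."""
    if n_synthetic <= 0:
        raise ValueError("n_synthetic must be positive")
    latent_dim = generator.layers[0].W.shape[0]
    z = generate_latent_points(latent_dim, n_synthetic, rng)
    out = generator(z)
    encoded = EncodedTable(out, list(codecs))
    return decode_table(encoded, name=name)
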