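"""GAN-ready encoding of expression tables and its inverse.

Continuous gene columns are mode-normalized: a Gaussian mixture is
fitted per column, each value is assigned to its highest-responsibility
component and rewritten as a standardized scalar ``(v - mean_k) /
(alpha * std_k)`` clipped to (-1, 1), concatenated with a one-hot mode
indicator.  Multi-modal expression columns thereby become unimodal in
the representation the generator has to learn.  The binary class label
is encoded as a categorical one-hot perturbed with small uniform noise
(and renormalized), so a single GAN jointly generates expression values
and labels.

A plain min-max variant (``method='minmax'``) maps each column linearly
onto [-1, 1]; it is expressed as a single-mode codec so the rest of the
pipeline is agnostic to the choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import BayesianGaussianMixture

from .io_expression import ExpressionTable

__all__ = ["ColumnCodec", "EncodedTable", "fit_codecs", "encode_table", "decode_table"]

CLIP = 0.99
STD_FLOOR = 1e-6
NOISE_AMPLITUDE = 0.2


@dataclass
class ColumnCodec:
    """Per-column encoder state: GMM modes or a category list."""

    name: str
    kind: str  # "continuous" | "categorical"
    mode_means: np.ndarray | None = None
    mode_stds: np.ndarray | None = None
    mode_weights: np.ndarray | None = None
    categories: list | None = None
    alpha: float = 2.0

    def __post_init__(self):
        if self.kind == "continuous":
            self.mode_means = np.asarray(self.mode_means, dtype=float)
            self.mode_stds = np.maximum(np.asarray(self.mode_stds, dtype=float), STD_FLOOR)
            self.mode_weights = np.asarray(self.mode_weights, dtype=float)
            self.mode_weights = self.mode_weights / self.mode_weights.sum()
            if np.any(self.mode_stds <= 0):
                raise ValueError(f"{self.name}: non-positive mode std")
        elif self.kind == "categorical":
            if not self.categories or len(set(self.categories)) != len(self.categories):
                raise ValueError(f"{self.name}: categories must be unique and non-empty")
        else:
            raise ValueError(f"unknown codec kind {self.kind!r}")

    @property
    def n_modes(self) -> int:
        return len(self.mode_means) if self.kind == "continuous" else 0

    @property
    def width(self) -> int:
        """Encoded width: scalar + mode one-hot, or category one-hot."""
        if self.kind == "continuous":
            return 1 + self.n_modes
        return len(self.categories)

    def to_dict(self) -> dict:
        if self.kind == "continuous":
            return {
                "name": self.name,
                "kind": self.kind,
                "alpha": self.alpha,
                "mode_means": self.mode_means.tolist(),
                "mode_stds": self.mode_stds.tolist(),
                "mode_weights": self.mode_weights.tolist(),
            }
        return {"name": self.name, "kind": self.kind, "categories": list(self.categories)}

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnCodec":
        return cls(**d)


@dataclass
class EncodedTable:
    """Row-major encoded matrix plus the codecs needed to invert it."""

    data: np.ndarray
    codecs: list[ColumnCodec]

    def __post_init__(self):
        if self.data.shape[1] != self.width:
            raise ValueError(
                f"encoded width {self.data.shape[1]} != codec width {self.width}"
            )

    @property
    def width(self) -> int:
        return sum(c.width for c in self.codecs)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


def _fit_continuous(x: np.ndarray, name: str, n_modes: int, alpha: float, seed: int) -> ColumnCodec:
    distinct = np.unique(x)
    k = int(min(n_modes, len(distinct)))
    if k <= 1 or np.std(x) == 0.0:
        return ColumnCodec(
            name, "continuous", [x.mean()], [max(x.std(), STD_FLOOR)], [1.0], alpha=alpha
        )
    # Dirichlet-process mixture: surplus components collapse to negligible
    # weight on unimodal columns and are pruned, so near-Gaussian genes get
    # a single mode instead of being fragmented across n_modes clusters.
    gmm = BayesianGaussianMixture(
        n_components=k,
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1e-3,
        random_state=seed,
        max_iter=200,
        reg_covar=1e-6,
    )
    gmm.fit(x.reshape(-1, 1))
    means = gmm.means_.ravel()
    stds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    keep = weights >= 1e-3  # prune negligible components
    if not keep.any():
        keep[np.argmax(weights)] = True
    return ColumnCodec(name, "continuous", means[keep], stds[keep], weights[keep], alpha=alpha)


def fit_codecs(
    table: ExpressionTable,
    n_modes: int = 5,
    seed: int = 0,
    alpha: float = 2.0,
    method: str = "gmm",
    label_name: str = "label",
) -> list[ColumnCodec]:
    """Fit one codec per gene column plus a categorical codec for the label.

    ``method='minmax'`` skips the mixture fit and produces single-mode
    codecs whose scalar encoding is the min-max map onto [-1, 1].
    Columns with fewer distinct values than ``n_modes`` are fitted with a
    reduced mode count; constant columns collapse to a single mode with a
    floored standard deviation.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if method not in ("gmm", "minmax"):
        raise ValueError(f"unknown encoding method {method!r}")
    codecs: list[ColumnCodec] = []
    for j, g in enumerate(table.gene_ids):
        x = table.values[:, j]
        if method == "minmax":
            lo, hi = float(x.min()), float(x.max())
            center = (lo + hi) / 2.0
            halfrange = max((hi - lo) / 2.0, STD_FLOOR)
            # scalar = (v - center) / (alpha * std) == (v - center)/halfrange
            codecs.append(
                ColumnCodec(g, "continuous", [center], [halfrange / alpha], [1.0], alpha=alpha)
            )
        else:
            codecs.append(_fit_continuous(x, g, n_modes, alpha, seed))
    codecs.append(ColumnCodec(label_name, "categorical", categories=[0, 1]))
    return codecs


def encode_table(
    table: ExpressionTable,
    codecs: list[ColumnCodec],
    rng: np.random.Generator | None = None,
) -> EncodedTable:
    """Encode a table through fitted codecs.

    Continuous cells become (clipped standardized scalar, mode one-hot)
    with the mode chosen by highest GMM responsibility; the label becomes
    a noisy renormalized one-hot.  ``rng`` drives the categorical noise;
    omit it for noise-free one-hots.
    """
    names = {c.name for c in codecs if c.kind == "continuous"}
    if set(table.gene_ids) != names:
        unknown = sorted(set(table.gene_ids) ^ names)
        raise ValueError(f"codec/table schema mismatch: {unknown[:5]}")
    col_of = {g: i for i, g in enumerate(table.gene_ids)}
    blocks: list[np.ndarray] = []
    n = table.n_samples
    for c in codecs:
        if c.kind == "continuous":
            v = table.values[:, col_of[c.name]]
            k = _responsibility_argmax(v, c)
            std = c.mode_stds[k]
            scalar = (v - c.mode_means[k]) / (c.alpha * std)
            scalar = np.clip(scalar, -CLIP, CLIP)
            onehot = np.zeros((n, c.n_modes))
            onehot[np.arange(n), k] = 1.0
            blocks.append(np.column_stack([scalar, onehot]))
        else:
            cat_index = {cat: i for i, cat in enumerate(c.categories)}
            idx = np.array([cat_index[int(l)] for l in table.labels])
            onehot = np.zeros((n, len(c.categories)))
            onehot[np.arange(n), idx] = 1.0
            if rng is not None:
                onehot = onehot + rng.uniform(0, NOISE_AMPLITUDE, onehot.shape)
                onehot = onehot / onehot.sum(axis=1, keepdims=True)
            blocks.append(onehot)
    return EncodedTable(np.hstack(blocks), list(codecs))


def _responsibility_argmax(v: np.ndarray, c: ColumnCodec) -> np.ndarray:
    """Index of the highest-responsibility mode for each value."""
    v = v[:, None]
    log_dens = (
        -0.5 * ((v - c.mode_means[None, :]) / c.mode_stds[None, :]) ** 2
        - np.log(c.mode_stds[None, :])
        + np.log(c.mode_weights[None, :])
    )
    return np.argmax(log_dens, axis=1)


def decode_table(
    encoded: EncodedTable,
    sample_ids: list[str] | None = None,
    name: str = "decoded",
) -> ExpressionTable:
    """Invert :func:`encode_table`: scalar·α·std_k + mean_k per cell,
    argmax over one-hot blocks for modes and categories."""
    data = encoded.data
    if data.shape[1] != encoded.width:
        raise ValueError("encoded width does not match codecs")
    cols: list[np.ndarray] = []
    gene_ids: list[str] = []
    labels = None
    pos = 0
    for c in encoded.codecs:
        w = c.width
        block = data[:, pos : pos + w]
        pos += w
        if c.kind == "continuous":
            scalar = np.clip(block[:, 0], -CLIP, CLIP)
            k = np.argmax(block[:, 1:], axis=1)
            cols.append(scalar * c.alpha * c.mode_stds[k] + c.mode_means[k])
            gene_ids.append(c.name)
        else:
            idx = np.argmax(block, axis=1)
            labels = np.array([c.categories[i] for i in idx], dtype=int)
    if labels is None:
        raise ValueError("codecs contain no categorical label column")
    values = np.column_stack(cols)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
    return ExpressionTable(values, gene_ids, sample_ids, labels, name=name)


def save_codecs(codecs: list[ColumnCodec], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in codecs], fh)


def load_codecs(path) -> list[ColumnCodec]:
    with open(path) as fh:
        return [ColumnCodec.from_dict(d) for d in json.load(fh)]
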