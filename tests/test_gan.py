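import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wtgan.encoding import encode_table, fit_codecs
from wtgan.gan import (
    GanConfig,
    adversarial_losses_gan,
    augment_table,
    critic_loss_wgan,
    generate_latent_points,
    generator_loss_wgan,
    make_fake_batch,
    make_real_batch,
    build_generator,
    sample_synthetic,
    train_wtgan,
)

from conftest import make_table

LN2 = float(np.log(2.0))


def encoded_toy(n=200, means=(0.0, 3.0), seed=42):
    rng = np.random.default_rng(seed)
    vals = np.column_stack([rng.normal(m, 1.0, n) for m in means])
    t = make_table(vals, rng.integers(0, 2, n))
    codecs = fit_codecs(t, n_modes=1, seed=0)
    return encode_table(t, codecs), codecs, t


class TestLatentPoints:
    def test_shape_contract(self):
        z = generate_latent_points(8, 4, np.random.default_rng(0))
        assert z.shape == (4, 8)

    def test_deterministic_from_seed_state(self):
        z1 = generate_latent_points(5, 7, np.random.default_rng(3))
        z2 = generate_latent_points(5, 7, np.random.default_rng(3))
        np.testing.assert_array_equal(z1, z2)

    def test_standard_normal_moments(self):
        z = generate_latent_points(4, 10_000, np.random.default_rng(1))
        assert np.abs(z.mean(axis=0)).max() < 0.05
        assert np.abs(z.var(axis=0) - 1.0).max() < 0.1


class TestBatches:
    def test_full_real_batch_is_permutation(self):
        enc, _, _ = encoded_toy(n=20)
        batch, y = make_real_batch(enc, 20, np.random.default_rng(0))
        assert np.all(y == 1)
        got = batch[np.lexsort(batch.T)]
        want = enc.data[np.lexsort(enc.data.T)]
        np.testing.assert_array_equal(got, want)

    def test_oversampling_raises(self):
        enc, _, _ = encoded_toy(n=10)
        with pytest.raises(ValueError):
            make_real_batch(enc, 11, np.random.default_rng(0))

    def test_different_seed_states_differ(self):
        enc, _, _ = encoded_toy(n=50)
        draws = {
            make_real_batch(enc, 5, np.random.default_rng(s))[0].tobytes()
            for s in range(10)
        }
        assert len(draws) > 1

    def test_fake_batch_contract(self):
        enc, _, _ = encoded_toy()
        gen = build_generator(16, enc.width, (32,), np.random.default_rng(0))
        batch, y = make_fake_batch(gen, 16, 6, np.random.default_rng(1))
        assert batch.shape == (6, enc.width)
        assert np.all(np.isfinite(batch)) and np.all(y == 0)
        batch2, _ = make_fake_batch(gen, 16, 6, np.random.default_rng(1))
        np.testing.assert_array_equal(batch, batch2)


class TestLosses:
    @pytest.mark.parametrize(
        "real,fake,expected",
        [([1, 1], [0, 0], -1.0), ([1, 1], [1, 1], 0.0), ([2], [-2], -4.0)],
    )
    def test_wgan_critic_arithmetic(self, real, fake, expected):
        assert critic_loss_wgan(np.array(real, float), np.array(fake, float)) == expected

    @pytest.mark.parametrize("fake,expected", [([0, 0], 0.0), ([1, 3], -2.0)])
    def test_wgan_generator_arithmetic(self, fake, expected):
        assert generator_loss_wgan(np.array(fake, float)) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_wgan_critic_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        r, f = rng.normal(size=6), rng.normal(size=6)
        assert critic_loss_wgan(r, f) == pytest.approx(-critic_loss_wgan(f, r))

    def test_generator_loss_monotone_in_scores(self):
        assert generator_loss_wgan(np.array([1.0, 3.0])) > generator_loss_wgan(
            np.array([2.0, 4.0])
        )

    def test_gan_losses_closed_forms(self):
        eps = 1e-7
        c, _ = adversarial_losses_gan(np.array([1 - eps]), np.array([eps]))
        assert c == pytest.approx(0.0, abs=1e-5)
        c, g = adversarial_losses_gan(np.array([0.5]), np.array([0.5]))
        assert c == pytest.approx(LN2)
        assert g == pytest.approx(LN2)


class TestTraining:
    def test_zero_epochs_returns_untrained_generator(self):
        enc, _, _ = encoded_toy(n=30)
        gen, hist = train_wtgan(enc, GanConfig(epochs=0, seed=1))
        assert len(hist) == 0
        out = gen(np.zeros((2, 64)))
        assert out.shape == (2, enc.width)

    @pytest.mark.parametrize("mode", ["wgan", "gan"])
    def test_history_length_and_finiteness(self, mode):
        enc, _, _ = encoded_toy(n=40)
        cfg = GanConfig(epochs=12, mode=mode, seed=2)
        _, hist = train_wtgan(enc, cfg)
        assert len(hist) == 12
        assert np.all(np.isfinite(hist.generator_loss))
        assert np.all(np.isfinite(hist.critic_loss))

    def test_reproducible_from_seed(self):
        enc, codecs, _ = encoded_toy(n=40)
        cfg = GanConfig(epochs=10, seed=5)
        g1, h1 = train_wtgan(enc, cfg)
        g2, h2 = train_wtgan(enc, cfg)
        assert h1.generator_loss == h2.generator_loss
        for w1, w2 in zip(g1.get_weights(), g2.get_weights()):
            np.testing.assert_array_equal(w1, w2)

    def test_wgan_weights_clipped_at_every_update(self):
        enc, _, _ = encoded_toy(n=40)
        cfg = GanConfig(epochs=8, seed=3, clip_value=0.01)
        seen = []

        def check(epoch, critic):
            seen.append(max(np.abs(p).max() for p in critic.params))

        train_wtgan(enc, cfg, callback=check)
        assert len(seen) == 8 * cfg.critic_steps
        assert max(seen) <= 0.01 + 1e-12

    def test_gan_mode_perfect_critic_gives_high_generator_loss(self):
        # a frozen discriminator that assigns fakes probability ~0 should
        # make the non-saturating generator loss large
        probs_bad = np.full(8, 1e-6)
        _, g_bad = adversarial_losses_gan(np.array([0.999]), probs_bad)
        _, g_good = adversarial_losses_gan(np.array([0.999]), np.full(8, 0.9))
        assert g_bad > g_good

    def test_moment_recovery_on_gaussian_toy(self):
        enc, codecs, t = encoded_toy(n=200, means=(0.0, 3.0))
        gen, _ = train_wtgan(enc, GanConfig(epochs=300, seed=7))
        syn = sample_synthetic(gen, codecs, 400, np.random.default_rng(7))
        assert syn.values[:, 0].mean() == pytest.approx(0.0, abs=0.5)
        assert syn.values[:, 1].mean() == pytest.approx(3.0, abs=0.5)

    def test_correlation_recovery_improves_with_training(self):
        # 5-gene table, planted correlation; synthetic correlation error
        # should shrink between epoch 50 and epoch 500 in >= 4 of 5 runs
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            shared = rng.normal(size=(120, 1))
            vals = 0.8 * shared + 0.6 * rng.normal(size=(120, 5))
            truth = np.corrcoef(vals, rowvar=False)
            t = make_table(vals, rng.integers(0, 2, 120))
            codecs = fit_codecs(t, n_modes=1, seed=seed)
            enc = encode_table(t, codecs)
            errs = {}
            for epochs in (50, 500):
                gen, _ = train_wtgan(enc, GanConfig(epochs=epochs, seed=seed))
                syn = sample_synthetic(gen, codecs, 400, np.random.default_rng(seed))
                c = np.corrcoef(syn.values, rowvar=False)
                errs[epochs] = np.linalg.norm(c - truth)
            wins += errs[500] < errs[50]
        assert wins >= 4


class TestSampleSynthetic:
    def test_contract_and_determinism(self):
        enc, codecs, _ = encoded_toy(n=60)
        gen, _ = train_wtgan(enc, GanConfig(epochs=5, seed=1))
        s1 = sample_synthetic(gen, codecs, 100, np.random.default_rng(9))
        s2 = sample_synthetic(gen, codecs, 100, np.random.default_rng(9))
        assert s1.n_samples == 100
        assert set(np.unique(s1.labels)) <= {0, 1}
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_nonpositive_count_raises(self):
        enc, codecs, _ = encoded_toy(n=30)
        gen, _ = train_wtgan(enc, GanConfig(epochs=0, seed=0))
        with pytest.raises(ValueError):
            sample_synthetic(gen, codecs, 0, np.random.default_rng(0))


class TestAugmentTable:
    def test_labels_exact_and_counts_proportional(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(40, 4))
        labels = np.array([0] * 30 + [1] * 10)
        t = make_table(vals, labels)
        syn = augment_table(t, GanConfig(epochs=5, seed=0), n_synthetic=20)
        assert syn.n_samples == 20
        assert (syn.labels == 0).sum() == 15 and (syn.labels == 1).sum() == 5
        assert syn.gene_ids == t.gene_ids

    def test_single_class_raises(self):
        t = make_table(np.random.default_rng(0).normal(size=(10, 3)), [1] * 10)
        with pytest.raises(ValueError, match="single class"):
            augment_table(t, GanConfig(epochs=1, seed=0), n_synthetic=4)
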