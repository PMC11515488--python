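# Methods

This note records the models, numerical choices and limitations behind
`wtgan`.  It is the package's own account of its procedures; every
number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Problem setting

Input is a labelled expression table: `n` samples (tens), `p` genes
(hundreds to thousands), a binary tumor/healthy label.  The package
asks whether adding GAN-generated samples to the training split improves
downstream classification, and provides the machinery to measure that
honestly: feature selection, encoding, adversarial training, synthetic
generation, a fixed-protocol benchmark and a real-vs-synthetic quality
report, all seeded end to end.

## Feature selection

Relevance is `|pearson_r(gene, label)|`; a point-biserial correlation,
since the label is binary.  Genes with zero variance have undefined
correlation; they score 0 and sort last rather than aborting a run,
because microarray exports routinely contain constant probes.
Redundancy elimination is a greedy scan in relevance order: a gene is
kept iff its absolute correlation with **every** already-kept gene is at
or below the threshold.  Greedy keep-first-by-relevance makes the result
deterministic and always discards the less label-informative member of a
correlated pair.  Absolute correlation is used for both stages:
anti-correlated duplicates are exactly as redundant as correlated ones.

The kept set is therefore pairwise weakly correlated, and kept-set size
grows monotonically with the threshold (property-tested).  Two optional
stages exist but default off: a relevance pre-filter (cutoff ζ, default
0 — the redundancy threshold alone determines the kept counts) and a
`max_features` cap, including the `n − ln n` variant some correlation
filters quote (`max_features_nlogn`); the cap cannot reproduce realistic
kept-set sizes on its own (2000 − ln 2000 ≈ 1992) and is provided only
as a truncation convenience.

The published per-dataset counts (colon 62×2000 at threshold 0.75 →
860 kept, leukemia 72×3572 at 0.65 → 1329, prostate 102×6033 at 0.7 →
1833) are asserted by `tests/test_acceptance.py` against CSVs fetched by
`scripts/fetch_datasets.py`; the pairwise-elimination order is not fully
specified in the published description, so an exact-match failure there
reports the achieved counts rather than hiding them.

## Encoding

Continuous columns are mode-normalized.  A Bayesian Gaussian mixture
(Dirichlet-process weight prior, at most `n_modes` = 5 components,
weight-concentration prior 10⁻³) is fitted per column; components with
weight < 10⁻³ are pruned, so unimodal columns collapse to a single mode
instead of being fragmented — with only ~20–40 rows per fit this
pruning is what keeps synthetic variance calibrated.  A value `v`
assigned to its highest-responsibility mode `k` encodes as
`((v − μ_k)/(α·σ_k), onehot(k))` with α = 2, clipped to ±0.99 so the
decoder stays finite; decoding inverts with `argmax` over the mode
indicator.  Encode→decode is exact (< 10⁻⁹, in practice machine epsilon)
for values within α·σ of their mode mean; values beyond the clip bound
are truncated to ±2σ of their mode, a deliberate tail compromise.
Constant columns get a single mode with the standard deviation floored
at 10⁻⁶.  The class label is a categorical one-hot with uniform(0, 0.2)
noise added and renormalized; the noise amplitude can never flip the
argmax of a binary one-hot.  A `minmax` method maps each column linearly
onto [−1, 1] (expressed as a single-mode codec) for users who prefer no
mixture model.  Encoded width is
`Σ_continuous (1 + n_modes_c) + Σ_categorical |categories|`.

The generator's output layer is linear and the decoder clips, rather
than using a tanh output; with clipping the two are equivalent at decode
time and the linear layer keeps the critic's gradients unsquashed.

## Networks and training

No deep-learning framework is used: the networks are dense multilayer
perceptrons implemented in numpy with manual backpropagation
(`wtgan.nn`).  Initialization is he_uniform (U(±√(6/fan_in))); hidden
activations are ReLU.  Generator: latent 64 → 128 → 256 → encoded width,
linear output.  Critic: width → 256 → 128 → 1, linear output in
Wasserstein mode, sigmoid in the standard-GAN baseline.

Per epoch, the critic takes `critic_steps` updates (default 5 in wgan
mode, 1 in gan mode), each a **single** optimizer step on the combined
loss over a half-batch of real rows (target 1) and a half-batch of
generated rows (target 0): `−(mean(D(x)) − mean(D(G(z))))` in wgan mode,
two-target binary cross-entropy in gan mode.  In wgan mode every weight
is hard-clipped to [−0.01, 0.01] after every update — the original
weight-clipping Lipschitz constraint; no gradient penalty is
implemented.  The generator then takes one step through the frozen
critic on a full batch: `−mean(D(G(z)))` in wgan mode, non-saturating
cross-entropy in gan mode.  Optimizers: RMSprop (lr 5·10⁻⁵) in wgan
mode, Adam (lr 2·10⁻⁴) in gan mode — the two optimizer conventions the
two objectives are normally paired with.  Defaults: 5000 epochs, batch
32 (half-batch 16); probabilities are clamped to [10⁻⁷, 1 − 10⁻⁷] in
cross-entropies; a non-finite loss aborts with the epoch named.  All
randomness — init, batch sampling, latent draws — flows from one seeded
generator, so training histories and weights replay exactly.

### Per-class generation

`augment_table` trains one GAN per class on the class's rows and labels
each synthetic sample by construction, with per-class counts
proportional to the training class frequencies.  The alternative —
one GAN generating the label jointly as a categorical column — is fully
supported (`train_wtgan` on a full encoded table) but measurably
unsuitable at small scale: the generated label block decouples from the
generated expression at the training lengths a 40-row table justifies,
and augmenting with effectively label-randomized samples collapsed the
benchmark (mean accuracy 0.83 → 0.65 on the simulation study).
Class-partition conditioning is the standard remedy in the
GAN-oversampling literature and is the package default.

GANs must be trained on the training split only; the pipeline splits
first (stratified, seeded) and the benchmark re-derives the identical
split from the same seed, so no synthetic row ever descends from a test
row.

## Benchmark protocol

`split_train_test` is stratified with train size ⌊0.7·n⌋ (both classes
always present on both sides).  Five classifiers — random forest, SVM
(RBF), logistic regression, decision tree, and a feed-forward network
(two hidden layers 64/32, 200 epochs) — run at ecosystem defaults with
fixed seeds; SVM, LR and the FFN are standardized in-pipeline.  Metrics
are accuracy, recall, precision, F1 for the positive (tumor) class,
computed from the confusion counts; zero-denominator cases return 0 and
set a `degenerate` flag.  Synthetic samples are appended to the training
split only, and every condition (original / tgan / wtgan) is evaluated
on the identical held-out real test set.

## Quality report

Per gene: |Δmean|, |Δstd|, and the empirical order-1 Wasserstein
distance between the real and synthetic marginals (mean absolute
difference of matched quantile functions).  Global: RMS difference of
the two gene-gene correlation matrices' upper triangles, and a
detection AUC — a standardized logistic regression cross-validated
5-fold on the pooled rows (real = 1, fake = 0), AUC averaged over
held-out folds so between-fold calibration offsets cannot bias it.
When the two tables have equal row counts, row *i* of each table is
assigned to the same fold: if the synthetic table were an exact copy,
every held-out twin pair receives identical scores and the AUC is
exactly 0.5, whereas row-independent folding lets the model memorize a
twin's training label and systematically invert the held-out score.
0.5 means indistinguishable; distances from 0.5 in either direction
indicate structure a detector can exploit.

## The simulator

`simulate_mgecd` draws class-conditional multivariate normals with
block-equicorrelated covariance: genes come in consecutive blocks of
`block_size` (default 20) with pairwise correlation `block_rho`
(default 0.8) inside a block and independence across blocks
(`g = √ρ·shared + √(1−ρ)·noise`, unit marginal variance); class 1 adds
`effect_size` (default 1.0) to the first `n_informative` genes (default
100).  Defaults mirror the target regime: 62 samples × 2000 genes,
balanced classes.  Ground truth (informative genes, block membership)
is returned so tests never re-derive it.  The simulator deliberately
omits probe-level noise, heavy tails, batch effects and real gene
identifiers — passing tests demonstrate the machinery recovers planted
structure, not that augmentation helps on any particular real dataset.

## What the augmentation study actually shows

At the desk-scale study conditions (60 samples × 500 genes, δ = 1.0,
500 epochs, 100 synthetic samples), the measured effect of WT-GAN
augmentation on mean held-out accuracy is small and learner-dependent:
averaged over 15 simulation seeds it is +0.4 ± 0.9 percentage points
(decision trees and random forests gain a couple of points; logistic
regression, already near-optimal on Gaussian class-conditional data,
loses slightly).  On clean Gaussian simulations a well-specified linear
model has little to gain from distribution-replicating augmentation;
the large gains reported for real microarray data do not transfer to
this idealized setting.  The directional acceptance test asserts
"augmented ≥ original" over five fixed seeds and sits exactly at this
noise floor.

## Numerical and degenerate-input choices

* Pearson correlation of a constant vector is NaN at the primitive
  level; rankers treat it as relevance 0, the redundancy filter treats
  it as non-redundant (zero-variance columns are L2-zero after
  centering).
* Redundancy comparisons use a 10⁻¹² tolerance above the threshold so
  floating-point equality at the boundary keeps, not drops.
* Columns with fewer distinct values than `n_modes` are fitted with a
  reduced component count; never an error.
* Batch size must be even (half-batch construction); requesting more
  real rows than exist in a batch raises instead of silently sampling
  with replacement.
* `epochs=0` returns an initialized, untrained generator with an empty
  history (useful for shape contracts).

## Known limitations

* Weight clipping (not gradient penalty) bounds the critic; it matches
  first moments quickly but is slow on second moments — synthetic
  variance overshoots early in training and contracts below the target
  under very long training.  Epoch counts in the low thousands are the
  practical operating range at these table sizes.
* The 1-D Wasserstein diagnostic is per-column; no multivariate
  optimal-transport distance is computed.
* The benchmark fixes classifier hyperparameters at library defaults;
  no tuning, no cross-validation beyond the fixed 70/30 protocol, no
  multiple-testing control on the feature filter.
* Real-data ingestion is CSV only (samples-as-rows by default,
  genes-as-rows via a flag); no raw microarray formats.
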