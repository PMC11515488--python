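"""Simulator for microarray-like labelled expression tables.

Emulates the regime the pipeline targets: few samples, thousands of
numeric gene columns, two classes.  Samples are drawn from
class-conditional multivariate normals with a block-equicorrelated
covariance (correlation ``rho`` within consecutive blocks of
``block_size`` genes, zero across blocks); class 1 has its mean shifted
by ``effect_size`` on the first ``n_informative`` genes.  Ground truth
(informative genes, block memberships) is returned so tests never have
to re-derive it.

The model deliberately omits probe-level noise, batch effects and heavy
tails; it exists to give every module a table with known correlation
and class structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_expression import ExpressionTable

__all__ = ["SimSpec", "GroundTruth", "simulate_mgecd"]


@dataclass
class SimSpec:
    """Parameters of one simulated dataset."""

    n_samples: int = 62
    n_features: int = 2000
    n_informative: int = 100
    effect_size: float = 1.0
    block_size: int = 20
    block_rho: float = 0.8
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie strictly between 0 and 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class GroundTruth:
    informative_genes: list[str]
    blocks: dict[str, int]  # gene id -> block index
    spec: SimSpec


def simulate_mgecd(spec: SimSpec) -> tuple[ExpressionTable, GroundTruth]:
    """Draw one labelled table from the class-conditional block model.

    Within a block, gene g = sqrt(rho)·shared + sqrt(1-rho)·noise gives
    pairwise correlation exactly rho; unit marginal variance throughout.
    Class-1 rows get ``effect_size`` added on the informative genes.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    n_blocks = int(np.ceil(p / spec.block_size))
    block_of = np.repeat(np.arange(n_blocks), spec.block_size)[:p]
    shared = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, p))
    values = np.sqrt(spec.block_rho) * shared[:, block_of] + np.sqrt(1 - spec.block_rho) * noise

    informative = np.arange(spec.n_informative)
    if spec.n_informative > 0:
        values[np.ix_(labels == 1, informative)] += spec.effect_size

    gene_ids = [f"g{j}" for j in range(p)]
    sample_ids = [f"s{i}" for i in range(n)]
    table = ExpressionTable(values, gene_ids, sample_ids, labels, name=f"sim(seed={spec.seed})")
    truth = GroundTruth(
        informative_genes=[gene_ids[j] for j in informative],
        blocks={gene_ids[j]: int(block_of[j]) for j in range(p)},
        spec=spec,
    )
    return table, truth
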