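"""Correlation-based feature selection for gene-expression tables.

Two stages: (1) relevance ranking — each gene is scored by the absolute
Pearson correlation of its expression vector with the binary class
label; (2) redundancy elimination — scanning the genes in relevance
order, a gene is kept only if its absolute pairwise correlation with
every previously kept gene stays at or below a threshold.  The kept set
is therefore pairwise weakly correlated and biased towards genes that
track the phenotype.

Absolute correlation is used throughout: a perfectly anti-correlated
duplicate carries no more information than a correlated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_expression import ExpressionTable

__all__ = [
    "FeatureSelectionResult",
    "pearson_r",
    "rank_relevance",
    "redundancy_filter",
    "select_features",
]


class EmptySelectionError(ValueError):
    """Every gene was eliminated by the configured filters."""


@dataclass
class FeatureSelectionResult:
    """Outcome of the relevance + redundancy pipeline."""

    relevance: dict[str, float]
    kept: list[str]
    dropped: list[str]
    redundancy_threshold: float
    relevance_cutoff: float = 0.0
    max_features: int | None = None

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_dict(self) -> dict:
        return {
            "redundancy_threshold": self.redundancy_threshold,
            "relevance_cutoff": self.relevance_cutoff,
            "max_features": self.max_features,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "kept": list(self.kept),
            "dropped": list(self.dropped),
            "relevance": {g: float(r) for g, r in self.relevance.items()},
        }


def pearson_r(v, u) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Returns ``nan`` when either vector is constant (zero variance): the
    correlation is undefined and the caller decides how to treat it.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if v.shape != u.shape or v.ndim != 1:
        raise ValueError("pearson_r expects two equal-length 1-D vectors")
    if v.size < 2:
        raise ValueError("pearson_r needs at least 2 observations")
    dv = v - v.mean()
    du = u - u.mean()
    denom = np.sqrt((dv * dv).sum() * (du * du).sum())
    if denom == 0.0:
        return float("nan")
    return float((dv * du).sum() / denom)


def _standardize_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize columns; constant columns become zero.

    With this scaling the Gram product of two columns is exactly their
    Pearson correlation, which lets the redundancy scan run as matrix
    products.
    """
    centered = values - values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    constant = norms == 0.0
    safe = np.where(constant, 1.0, norms)
    return centered / safe, constant


def rank_relevance(table: ExpressionTable) -> list[tuple[str, float]]:
    """Score every gene by |Pearson r| against the class label.

    Returns (gene_id, score) pairs sorted by descending score, ties
    broken by original column order.  Constant genes (undefined
    correlation) score 0 and sort last.
    """
    cols, constant = _standardize_columns(table.values)
    y = table.labels.astype(float)
    dy = y - y.mean()
    ynorm = np.linalg.norm(dy)
    if ynorm == 0.0:
        scores = np.zeros(table.n_genes)
    else:
        scores = np.abs(cols.T @ (dy / ynorm))
        scores[constant] = 0.0
    order = np.lexsort((np.arange(table.n_genes), -scores))
    return [(table.gene_ids[i], float(scores[i])) for i in order]


def redundancy_filter(
    table: ExpressionTable, ranking: list[str], threshold: float
) -> FeatureSelectionResult:
    """Greedy pairwise-correlation filter in ranking order.

    A gene is kept iff |pearson_r| with every already-kept gene is at or
    below ``threshold``.  Deterministic given the ranking.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if sorted(ranking) != sorted(table.gene_ids):
        raise ValueError("ranking must be a permutation of the table's genes")
    col_of = {g: i for i, g in enumerate(table.gene_ids)}
    cols, constant = _standardize_columns(table.values)
    n = table.n_genes
    kept_cols = np.empty((table.n_samples, n))
    kept: list[str] = []
    dropped: list[str] = []
    for g in ranking:
        j = col_of[g]
        c = cols[:, j]
        if kept and not constant[j]:
            r = np.abs(kept_cols[:, : len(kept)].T @ c)
            # constant genes have zero columns -> r = 0 vs them (undefined treated as non-redundant)
            if np.any(r > threshold + 1e-12):
                dropped.append(g)
                continue
        kept_cols[:, len(kept)] = c
        kept.append(g)
    relevance = dict(rank_relevance(table))
    return FeatureSelectionResult(
        relevance=relevance, kept=kept, dropped=dropped, redundancy_threshold=threshold
    )


def select_features(
    table: ExpressionTable,
    threshold: float = 0.75,
    relevance_cutoff: float = 0.0,
    max_features: int | None = None,
) -> tuple[ExpressionTable, FeatureSelectionResult]:
    """Full pipeline: relevance ranking → optional relevance pre-filter →
    greedy redundancy filter → optional cap on the number of kept genes.

    Returns the column-subsetted table and the selection record.  Genes
    removed by the relevance pre-filter or the cap are counted as
    dropped.
    """
    ranked = rank_relevance(table)
    relevance = dict(ranked)
    if relevance_cutoff > 0:
        prefiltered = [g for g, s in ranked if s > relevance_cutoff]
    else:
        prefiltered = [g for g, _ in ranked]
    kept_pre = set(prefiltered)
    pre_dropped = [g for g, _ in ranked if g not in kept_pre]
    if not prefiltered:
        raise EmptySelectionError("relevance cutoff removed every gene")
    sub = table.subset_genes(prefiltered)
    res = redundancy_filter(sub, prefiltered, threshold)
    kept = res.kept
    capped: list[str] = []
    if max_features is not None and len(kept) > max_features:
        capped = kept[max_features:]
        kept = kept[:max_features]
    if not kept:
        raise EmptySelectionError("all genes eliminated")
    dropped = pre_dropped + res.dropped + capped
    result = FeatureSelectionResult(
        relevance=relevance,
        kept=kept,
        dropped=dropped,
        redundancy_threshold=threshold,
        relevance_cutoff=relevance_cutoff,
        max_features=max_features,
    )
    return table.subset_genes(kept), result


def max_features_nlogn(n_features: int) -> int:
    """The optional 'n − log n' stopping cap (natural log), rounded."""
    return int(round(n_features - np.log(n_features)))
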