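"""Real-vs-synthetic similarity diagnostics.

Per gene: absolute difference of means and standard deviations, and the
empirical 1-D Wasserstein (earth mover's) distance between the real and
synthetic marginals.  Globally: the RMS difference between the two
gene-gene correlation matrices (upper triangles) and a detection AUC —
the cross-validated ROC AUC of a classifier trained to tell real rows
from synthetic ones, where 0.5 means indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io_expression import ExpressionTable

__all__ = ["QualityReport", "wasserstein_1d", "quality_report"]


@dataclass
class QualityReport:
    per_gene: pd.DataFrame  # columns: gene, mean_abs_diff, std_abs_diff, wasserstein_1d
    correlation_rmse: float
    detection_auc: float

    def to_dict(self) -> dict:
        return {
            "correlation_rmse": float(self.correlation_rmse),
            "detection_auc": float(self.detection_auc),
            "per_gene": self.per_gene.to_dict(orient="list"),
        }


def wasserstein_1d(x, y) -> float:
    """Empirical first-order Wasserstein distance between two samples.

    For equal sizes this is the mean absolute difference of matched
    order statistics; in general it is the integral of the absolute
    difference of the two empirical quantile functions.  Symmetric, and
    zero iff the empirical distributions coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wasserstein_1d requires non-empty samples")
    return float(wasserstein_distance(x, y))


def _upper_triangle_corr(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)  # constant columns: undefined -> 0
    iu = np.triu_indices_from(c, k=1)
    return c[iu]


def quality_report(real: ExpressionTable, fake: ExpressionTable, seed: int = 0) -> QualityReport:
    """Compare a synthetic table against the real one it imitates."""
    if real.gene_ids != fake.gene_ids:
        raise ValueError("real and fake tables must share the same gene schema")
    rows = []
    for j, g in enumerate(real.gene_ids):
        xr, xf = real.values[:, j], fake.values[:, j]
        rows.append(
            {
                "gene": g,
                "mean_abs_diff": float(abs(xr.mean() - xf.mean())),
                "std_abs_diff": float(abs(xr.std() - xf.std())),
                "wasserstein_1d": wasserstein_1d(xr, xf),
            }
        )
    per_gene = pd.DataFrame(rows)

    tri_r = _upper_triangle_corr(real.values)
    tri_f = _upper_triangle_corr(fake.values)
    corr_rmse = float(np.sqrt(np.mean((tri_r - tri_f) ** 2))) if tri_r.size else 0.0

    auc = _detection_auc(real.values, fake.values, seed)
    return QualityReport(per_gene=per_gene, correlation_rmse=corr_rmse, detection_auc=auc)


def _detection_auc(real: np.ndarray, fake: np.ndarray, seed: int, n_splits: int = 5) -> float:
    """Cross-validated real-vs-fake AUC, averaged over held-out folds.

    AUC is computed within each fold, so between-fold calibration offsets
    never enter the comparison.  With equal row counts, row i of each
    table shares a fold ("twins" travel together): if the fake table is a
    copy of the real one, every held-out twin pair gets identical scores
    and the AUC is exactly the chance level 0.5, instead of being skewed
    by the model memorizing a twin's training label.
    """
    rng = np.random.default_rng(seed)
    X = np.vstack([real, fake])
    y = np.concatenate([np.ones(len(real)), np.zeros(len(fake))])
    clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=500, random_state=seed))

    if len(real) == len(fake):
        groups = rng.permutation(len(real))
        fold_of_group = groups % n_splits
        fold_of_row = np.concatenate([fold_of_group, fold_of_group])
        folds = [
            (np.where(fold_of_row != k)[0], np.where(fold_of_row == k)[0])
            for k in range(n_splits)
        ]
    else:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(cv.split(X, y))

    aucs = []
    for train_idx, test_idx in folds:
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        aucs.append(roc_auc_score(y[test_idx], scores))
    return float(np.mean(aucs))
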