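"""Downstream classifier benchmark over augmentation conditions.

Five classifiers (random forest, SVM, logistic regression, decision
tree, feed-forward neural network) are trained on the real training
split, optionally augmented with synthetic samples, and always
evaluated on the held-out real test split.  Metrics are accuracy,
recall, precision and F1 for the positive (tumor) class, computed from
the confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_expression import ExpressionTable, split_train_test

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "train_classifier",
    "run_benchmark",
    "CLASSIFIERS",
]

CLASSIFIERS = ("RF", "SVM", "LR", "DT", "FFN")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    """Benchmark results: one row per (condition, classifier)."""

    rows: list[dict]
    seed: int
    train_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def mean_accuracy(self, condition: str) -> float:
        accs = [r["accuracy"] for r in self.rows if r["condition"] == condition]
        if not accs:
            raise KeyError(f"no rows for condition {condition!r}")
        return float(np.mean(accs))


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with positive class = 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, recall, precision, F1 from confusion counts.

    accuracy  = (TP+TN) / (TP+TN+FP+FN)
    recall    = TP / (TP+FN)
    precision = TP / (TP+FP)
    f1        = 2·precision·recall / (precision+recall)

    A zero denominator yields 0 for that metric with ``degenerate=True``.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.TP + c.TN) / c.total
    degenerate = False
    if c.TP + c.FN == 0:
        recall, degenerate = 0.0, True
    else:
        recall = c.TP / (c.TP + c.FN)
    if c.TP + c.FP == 0:
        precision, degenerate = 0.0, True
    else:
        precision = c.TP / (c.TP + c.FP)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": acc,
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "degenerate": degenerate,
    }


def _make_model(kind: str, seed: int):
    if kind == "RF":
        return RandomForestClassifier(random_state=seed)
    if kind == "SVM":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    if kind == "LR":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed))
    if kind == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "FFN":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(64, 32),
                max_iter=200,
                early_stopping=False,
                random_state=seed,
            ),
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_classifier(kind: str, train: ExpressionTable, seed: int = 0):
    """Fit one of the benchmark classifiers; predictions are in {0, 1}."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set contains a single class")
    model = _make_model(kind, seed)
    model.fit(train.values, train.labels)
    return model


def _stack_training(real_train: ExpressionTable, synthetic: ExpressionTable | None,
                    ) -> ExpressionTable:
    if synthetic is None or synthetic.n_samples == 0:
        return real_train
    if synthetic.gene_ids != real_train.gene_ids:
        raise ValueError("synthetic table gene schema differs from the real table")
    values = np.vstack([real_train.values, synthetic.values])
    labels = np.concatenate([real_train.labels, synthetic.labels])
    ids = list(real_train.sample_ids) + [f"syn{i}" for i in range(synthetic.n_samples)]
    return ExpressionTable(values, list(real_train.gene_ids), ids, labels, real_train.name)


def run_benchmark(
    real: ExpressionTable,
    synthetic_by_condition: dict[str, ExpressionTable | None],
    train_fraction: float = 0.7,
    seed: int = 0,
    classifiers: tuple[str, ...] = CLASSIFIERS,
) -> EvalReport:
    """Train/evaluate every classifier under every augmentation condition.

    Synthetic samples are appended to the real 70% training split only;
    the 30% test split is always real, so conditions are compared on an
    identical held-out set.
    """
    train, test = split_train_test(real, train_fraction, seed)
    rows: list[dict] = []
    for condition, synthetic in synthetic_by_condition.items():
        augmented = _stack_training(train, synthetic)
        for kind in classifiers:
            model = train_classifier(kind, augmented, seed)
            pred = np.asarray(model.predict(test.values), dtype=int)
            m = metrics(confusion(test.labels, pred))
            rows.append(
                {
                    "dataset": real.name,
                    "condition": condition,
                    "classifier": kind,
                    "n_train_real": train.n_samples,
                    "n_train_synthetic": 0 if synthetic is None else synthetic.n_samples,
                    "n_test": test.n_samples,
                    **{k: m[k] for k in ("accuracy", "recall", "precision", "f1")},
                    "degenerate": m["degenerate"],
                }
            )
    return EvalReport(rows=rows, seed=seed, train_fraction=train_fraction)
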