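"""Reading, validating and splitting labelled gene-expression tables.

The canonical layout is a delimited text file with a header row, one
binary class-label column and one numeric column per gene, samples as
rows.  Tables stored genes-as-rows (genes in the first column, one
column per sample) are supported through an explicit orientation flag
and transposed on load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "ExpressionTable",
    "SchemaError",
    "load_table",
    "write_table",
    "split_train_test",
]


class SchemaError(ValueError):
    """Raised when a table violates the expected labelled-matrix schema."""


@dataclass
class ExpressionTable:
    """A samples × genes expression matrix with a binary class label.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression intensities (dimensionless).
    gene_ids : list of str
        Unique gene identifiers, one per column.
    sample_ids : list of str
        Sample identifiers, one per row.
    labels : ndarray of shape (n_samples,)
        Binary class per sample: 0 = healthy, 1 = tumor.
    name : str
        Dataset tag used in reports.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    name: str = "table"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise SchemaError(
                f"{self.name}: {n} rows but {len(self.labels)} labels / "
                f"{len(self.sample_ids)} sample ids"
            )
        if len(self.gene_ids) != p:
            raise SchemaError(f"{self.name}: {p} columns but {len(self.gene_ids)} gene ids")
        if len(set(self.gene_ids)) != p:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise SchemaError(f"{self.name}: duplicate gene ids {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise SchemaError(
                f"{self.name}: non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )
        classes = set(np.unique(self.labels).tolist())
        if not classes <= {0, 1} or len(classes) == 0:
            raise SchemaError(f"{self.name}: labels must be binary 0/1, got {sorted(classes)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionTable":
        """Column-subset to ``gene_ids``, preserving the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise SchemaError(f"{self.name}: unknown genes {missing[:5]}")
        cols = [idx[g] for g in gene_ids]
        return ExpressionTable(
            self.values[:, cols], list(gene_ids), list(self.sample_ids), self.labels, self.name
        )

    def subset_samples(self, rows: np.ndarray) -> "ExpressionTable":
        rows = np.asarray(rows)
        return ExpressionTable(
            self.values[rows],
            list(self.gene_ids),
            [self.sample_ids[i] for i in rows],
            self.labels[rows],
            self.name,
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.gene_ids, index=self.sample_ids)
        df.insert(0, label_column, self.labels)
        return df


def _coerce_labels(raw: pd.Series, positive_label: str | None) -> np.ndarray:
    """Map an arbitrary two-valued label column to {0, 1}.

    Numeric 0/1 pass through.  Otherwise the positive class is
    ``positive_label`` if given, else the lexicographically larger value.
    """
    uniq = pd.unique(raw)
    if len(uniq) > 2:
        raise SchemaError(f"label column has {len(uniq)} distinct values; expected 2")
    as_num = pd.to_numeric(raw, errors="coerce")
    if not as_num.isna().any() and set(np.unique(as_num)) <= {0.0, 1.0}:
        return as_num.to_numpy(dtype=int)
    svals = raw.astype(str)
    if positive_label is None:
        positive_label = sorted(svals.unique())[-1]
    elif positive_label not in set(svals.unique()):
        raise SchemaError(f"positive label {positive_label!r} not present in label column")
    return (svals == positive_label).to_numpy(dtype=int)


def load_table(
    path,
    label_column: str = "label",
    orientation: str = "samples-as-rows",
    positive_label: str | None = None,
    name: str | None = None,
) -> ExpressionTable:
    """Load a labelled expression CSV into an :class:`ExpressionTable`.

    ``orientation='genes-as-rows'`` expects gene identifiers in the first
    column and one column per sample, with labels in the row whose
    identifier equals ``label_column``; the matrix is transposed so that
    samples are rows.
    """
    if orientation not in ("samples-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path)
    if orientation == "genes-as-rows":
        # first column holds gene ids; the row with id == label_column holds labels
        wide = df.set_index(df.columns[0]).T
        wide.columns.name = None
        sample_ids = [str(s) for s in wide.index]
        df = wide.reset_index(drop=True)
    else:
        sample_ids = [str(i) for i in range(len(df))]
    if label_column not in df.columns:
        raise SchemaError(f"label column {label_column!r} not found in {path}")
    labels = _coerce_labels(df[label_column], positive_label)
    genes = df.drop(columns=[label_column])
    numeric = genes.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise SchemaError(
            f"non-numeric value at row {r} ({sample_ids[r]!r}), column {genes.columns[c]!r}"
        )
    return ExpressionTable(
        numeric.to_numpy(dtype=float),
        [str(c) for c in genes.columns],
        sample_ids,
        labels,
        name=name or str(path),
    )


def write_table(table: ExpressionTable, path, label_column: str = "label") -> None:
    """Write the table as samples-as-rows CSV with a leading label column."""
    table.to_frame(label_column).to_csv(path, index=False)


def split_train_test(
    table: ExpressionTable, train_fraction: float = 0.7, seed: int = 0
) -> tuple[ExpressionTable, ExpressionTable]:
    """Stratified train/test split of the samples.

    The split is deterministic for a fixed seed; train size is
    ``floor(train_fraction * n)`` with per-class proportional allocation,
    so both classes appear on both sides.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    counts = np.bincount(table.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples for a stratified split")
    idx = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=table.labels, random_state=seed
    )
    return table.subset_samples(np.sort(train_idx)), table.subset_samples(np.sort(test_idx))
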