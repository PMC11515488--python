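import numpy as np
import pytest

from wtgan.io_expression import ExpressionTable


def make_table(values, labels, name="t"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionTable(
        values, [f"g{j}" for j in range(p)], [f"s{i}" for i in range(n)],
        np.asarray(labels, dtype=int), name=name,
    )


@pytest.fixture
def tiny_table():
    """3 samples x 2 genes, labels [0, 1, 1]."""
    return make_table([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]], [0, 1, 1])


@pytest.fixture
def gaussian_toy():
    """200 samples x 2 genes: N(0,1) and N(3,1), balanced random labels."""
    rng = np.random.default_rng(42)
    vals = np.column_stack([rng.normal(0, 1, 200), rng.normal(3, 1, 200)])
    labels = np.zeros(200, dtype=int)
    labels[100:] = 1
    return make_table(vals, labels, name="gaussian-toy")
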