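import numpy as np
import pytest

from pclda.io_formats import CountMatrix, LabelVector
from pclda.preprocess import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_expr(values, cell_prefix="c", gene_prefix="g"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        np.array([f"{cell_prefix}{i}" for i in range(n)], dtype=object),
        np.array([f"{gene_prefix}{j}" for j in range(p)], dtype=object),
    )


def make_counts(values, cell_prefix="c", gene_prefix="g"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return CountMatrix(
        values,
        np.array([f"{cell_prefix}{i}" for i in range(n)], dtype=object),
        np.array([f"{gene_prefix}{j}" for j in range(p)], dtype=object),
    )


def make_labels(labels):
    return LabelVector(np.asarray(labels, dtype=object))


@pytest.fixture
def gaussian_classes(rng):
    """Well-separated 3-class Gaussian scores in 5 dimensions, 60 cells."""
    centers = np.array(
        [[4.0, 0, 0, 0, 0], [0, 4.0, 0, 0, 0], [0, 0, 4.0, 0, 0]]
    )
    z = np.vstack([rng.normal(c, 1.0, size=(20, 5)) for c in centers])
    labels = make_labels(np.repeat(["A", "B", "C"], 20))
    return z, labels
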