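import numpy as np
import pytest

from rots.io_counts import CountMatrix, GroupDesign
from rots.normalize import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts():
    """6 genes x 4 samples, deterministic, no zero rows."""
    values = np.array(
        [
            [10, 12, 8, 11],
            [100, 90, 110, 95],
            [5, 4, 6, 7],
            [1000, 1100, 950, 1020],
            [3, 2, 4, 1],
            [50, 55, 48, 52],
        ]
    )
    return CountMatrix(
        [f"g{i}" for i in range(6)], ["s1", "s2", "s3", "s4"], values
    )


@pytest.fixture
def design22():
    return GroupDesign(
        ["s1", "s2", "s3", "s4"], np.array([1, 1, 2, 2]), {1: "A", 2: "B"}
    )


@pytest.fixture
def design33():
    return GroupDesign(
        ["s1", "s2", "s3", "s4", "s5", "s6"],
        np.array([1, 1, 1, 2, 2, 2]),
        {1: "A", 2: "B"},
    )


def make_expression(values, sample_prefix="s"):
    """ExpressionMatrix from a raw array with generated ids."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        [f"g{i}" for i in range(g)],
        [f"{sample_prefix}{j + 1}" for j in range(n)],
        values,
    )


@pytest.fixture
def expr33(rng):
    """20 genes x 6 samples of gaussian noise."""
    return make_expression(rng.normal(size=(20, 6)))
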