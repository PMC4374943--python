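import numpy as np
import pytest

from hollownet import AbundanceMatrix, IncidenceMatrix


def labeled(values, prefix_r="sp", prefix_c="h", cls=AbundanceMatrix):
    """Wrap a plain array with generated labels."""
    arr = np.asarray(values)
    return cls(
        arr,
        tuple(f"{prefix_r}{i}" for i in range(arr.shape[0])),
        tuple(f"{prefix_c}{j}" for j in range(arr.shape[1])),
    )


@pytest.fixture
def triangle3():
    """Perfectly packed 3x3 staircase."""
    return labeled([[1, 1, 1], [1, 1, 0], [1, 0, 0]], cls=IncidenceMatrix)


@pytest.fixture
def identity3():
    return labeled(np.eye(3, dtype=int), cls=IncidenceMatrix)


@pytest.fixture
def two_blocks():
    """Two disjoint complete 2x2 blocks (planted two-module network)."""
    return labeled(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
        cls=IncidenceMatrix,
    )


def random_abundance(rng, max_rows=12, max_cols=12, fill=0.5, max_count=9):
    """Random abundance matrix with at least one positive cell."""
    while True:
        n_r = int(rng.integers(2, max_rows + 1))
        n_c = int(rng.integers(2, max_cols + 1))
        vals = (rng.random((n_r, n_c)) < fill) * rng.integers(1, max_count + 1, (n_r, n_c))
        if vals.sum() > 0:
            return labeled(vals)
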