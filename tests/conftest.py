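import numpy as np
import pytest

from sere import CountMatrix, make_synthetic_pool


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """2 bins x 2 lanes with equal lane totals; hand-computable SERE."""
    return CountMatrix(
        bin_ids=["exon1", "exon2"],
        lane_ids=["laneA", "laneB"],
        counts=[[10, 6], [4, 8]],
    )


@pytest.fixture
def singleton_matrix() -> CountMatrix:
    """Equal lane totals; first bin is a singleton (counts 1, 0)."""
    return CountMatrix(
        bin_ids=["s", "x"],
        lane_ids=["laneA", "laneB"],
        counts=[[1, 0], [9, 10]],
    )


@pytest.fixture(scope="session")
def small_pool():
    """A small but still heavy-tailed synthetic pool for fast simulations."""
    return make_synthetic_pool(n_bins=3_000, pool_size=300_000, seed=1234)


def random_count_matrix(
    rng: np.random.Generator, max_bins: int = 6, max_lanes: int = 3, max_count: int = 5
) -> CountMatrix:
    """A random small count matrix (the oracle-equivalence search space)."""
    n = rng.integers(1, max_bins + 1)
    m = rng.integers(2, max_lanes + 1)
    counts = rng.integers(0, max_count + 1, size=(n, m))
    return CountMatrix(
        bin_ids=[f"b{i}" for i in range(n)],
        lane_ids=[f"l{j}" for j in range(m)],
        counts=counts,
    )
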