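import numpy as np
import pytest

from chartmetrics import (
    build_wcs_grid,
    factor_similarity,
    ground_distance_matrix,
    similarity_matrix,
    synthetic_lab_coordinates,
)


@pytest.fixture(scope="session")
def grid():
    return build_wcs_grid()


@pytest.fixture(scope="session")
def lab(grid):
    return synthetic_lab_coordinates(grid)


@pytest.fixture(scope="session")
def ground(lab):
    return ground_distance_matrix(lab)


@pytest.fixture(scope="session")
def kernel(ground):
    return similarity_matrix(ground)


@pytest.fixture(scope="session")
def operator(kernel):
    return factor_similarity(kernel)


def random_chart_values(rng, n, max_support=6, integer=False):
    """Random sparse nonnegative chart vector with nonzero total mass."""
    support = rng.choice(n, size=rng.integers(1, max_support + 1), replace=False)
    v = np.zeros(n)
    if integer:
        v[support] = rng.integers(1, 10, size=len(support)).astype(float)
    else:
        v[support] = rng.uniform(0.1, 1.0, size=len(support))
    return v
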