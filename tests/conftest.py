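import numpy as np
import pytest

from baynorm import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cm():
    """4 genes x 3 cells with a zero row and a zero entry."""
    values = np.array(
        [
            [0, 1, 2],
            [5, 0, 3],
            [0, 0, 0],
            [10, 20, 30],
        ]
    )
    return CountMatrix(
        values,
        gene_ids=np.array([f"g{i}" for i in range(4)], dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(3)], dtype=object),
    )


# (x, mu, phi, beta) grid shared by the posterior oracle and moment tests
PARAM_GRID = [
    (x, mu, phi, beta)
    for x in (0, 1, 5)
    for mu in (1.0, 10.0)
    for phi in (0.5, 2.0, 50.0)
    for beta in (0.05, 0.3, 0.9)
]


@pytest.fixture(scope="session")
def param_grid():
    return PARAM_GRID
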