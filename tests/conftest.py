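import numpy as np
import pytest

from covdrift.coverage import WeightedPositionalDistribution


def random_distribution(
    rng: np.random.Generator, n_max: int = 30, lattice: int = 1000
) -> WeightedPositionalDistribution:
    """Random weighted positional distribution on a 1/lattice position grid.

    Lattice positions keep dense-grid oracle evaluation exact (every ECDF
    step falls on a grid point).
    """
    n = rng.integers(2, n_max + 1)
    positions = (
        np.sort(rng.choice(np.arange(1, lattice + 1), size=n, replace=False))
        / lattice
    )
    weights = rng.dirichlet(np.ones(n))
    return WeightedPositionalDistribution(positions, weights)


def grid_ks_oracle(a, b, n_grid: int = 10_000) -> float:
    """Brute-force sup |F_a - F_b| on a dense evaluation grid.

    Independent of the implementation under test: evaluates both
    right-continuous weighted ECDFs point by point.
    """
    grid = np.linspace(1.0 / n_grid, 1.0, n_grid)

    def ecdf(dist):
        # F(x) = sum of weights at positions <= x, via explicit indicator matrix
        indicator = dist.positions[None, :] <= grid[:, None]
        return indicator @ dist.weights

    return float(np.abs(ecdf(a) - ecdf(b)).max())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
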