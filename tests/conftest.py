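import numpy as np
import pytest

from spectrasvg import (
    SpatialVariabilityTest,
    build_bandwidth_ladder,
    compute_basis_moments,
    grid_coordinates,
    sample_basis,
)


@pytest.fixture(scope="session")
def grid20():
    return grid_coordinates(20)


@pytest.fixture(scope="session")
def small_basis(grid20):
    """A modest multi-scale basis on the 20x20 grid (D=60, L=3)."""
    ladder = build_bandwidth_ladder(1.0, 8.0, 3)
    return sample_basis(ladder, 60, seed=42)


@pytest.fixture(scope="session")
def small_moments(grid20, small_basis):
    return compute_basis_moments(small_basis, grid20, subsample_size=10_000, seed=0)


@pytest.fixture(scope="session")
def fitted20(grid20):
    """Default-ish estimator fitted on the 20x20 grid, shared across tests."""
    return SpatialVariabilityTest(
        n_features=120, n_scales=5, random_state=7
    ).fit(grid20)
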