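import numpy as np
import pytest

from mineforest.grids import FineRasterStack
from mineforest.landscape import LandscapeConfig, generate_covariates, place_leases, simulate_loss


@pytest.fixture(scope="session")
def small_config():
    """A 20 x 20 km landscape that exercises every stage quickly."""
    return LandscapeConfig(
        width=20_000.0,
        height=20_000.0,
        n_years=10,
        buffer_distance=2_500.0,
        n_lml=1,
        n_lel=4,
        n_ssl=1,
        n_regions=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    cov = generate_covariates(small_config)
    leases = place_leases(small_config, cov)
    stack, effects = simulate_loss(small_config, cov, leases)
    return cov, leases, stack, effects


@pytest.fixture()
def random_stack():
    """60 x 60-cell random fine raster with 4 loss years."""
    rng = np.random.default_rng(42)
    tc = rng.uniform(0, 100, (60, 60))
    ly = rng.choice(np.arange(5), size=(60, 60), p=[0.72, 0.07, 0.07, 0.07, 0.07])
    return FineRasterStack(tc, ly, cell_size=25.0)
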