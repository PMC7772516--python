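import numpy as np
import pytest

from hypometa.simulate import SimulationConfig, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """10x12x10 grid at 2 mm spacing, origin-centred."""
    return make_grid((10, 12, 10), 2.0)


@pytest.fixture
def tiny_config():
    """Fast-but-structured simulation settings shared across tests."""
    return SimulationConfig(
        grid_shape=(16, 18, 16),
        n_experiments=10,
        n_genes=500,
        n_samples_per_donor=60,
        planted_set_size=50,
        n_marker_samples=120,
        seed=7,
    )
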