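import numpy as np
import pytest

import lynxcast as lx


@pytest.fixture(scope="session")
def small_config():
    """A compact study: one region per area, a dozen censuses."""
    return lx.SimulationConfig(
        regions_per_area=(1, 1, 1),
        n_years=12,
        initial_fg=(30.0, 25.0, 20.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    data, truth = lx.simulate_dataset(small_config)
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_data):
    """A quick 2-chain fit shared by posterior-consuming tests."""
    data, truth = small_data
    settings = lx.FitSettings(
        n_chains=2, n_iter=2500, n_burnin=1200, thin=5, seed=3
    )
    return lx.fit(data, settings=settings), data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
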