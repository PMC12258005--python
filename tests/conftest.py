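import numpy as np
import pytest

from caldose import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def small_config():
    """4x4 grid, modest cohort: fast enough for the multivariable fits."""
    return SimulationConfig(nx=4, ny=4, n_obs=120, seed=3, tumor_exclusion_radius=1)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
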