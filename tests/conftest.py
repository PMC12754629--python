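import numpy as np
import pytest
from hypothesis import settings

from salbef import SimulationConfig, simulate_experiment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_experiment(default_config):
    """One full simulated experiment under the default study design."""
    return simulate_experiment(default_config)


@pytest.fixture(scope="session")
def noiseless_null_config():
    """theta = phi = 0, noise off: the zero-NBE ground-truth scenario."""
    return SimulationConfig(
        seed=11,
        theta_by_salinity={},
        phi_by_salinity={},
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_null_experiment(noiseless_null_config):
    return simulate_experiment(noiseless_null_config)
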