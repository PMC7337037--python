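import numpy as np
import pytest

from slodrsim import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def clean_population():
    """Mid-sized one-factor population with no disturbance."""
    config = SimulationConfig(n_individuals=5_000, n_tests=15,
                              disturbance_shape="none", seed=101)
    return simulate_population(config)


@pytest.fixture(scope="session")
def disturbed_population():
    """Population attenuated by negatively skewed disturbance."""
    config = SimulationConfig(n_individuals=5_000, n_tests=15,
                              disturbance_shape="negative", seed=102)
    return simulate_population(config)


@pytest.fixture(scope="session")
def big_clean_population():
    """Large sample for parameter-recovery and moment checks."""
    config = SimulationConfig(n_individuals=100_000, n_tests=8,
                              disturbance_shape="none", seed=103)
    return simulate_population(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
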