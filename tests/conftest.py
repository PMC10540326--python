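import numpy as np
import pytest

from happi import HappiConfig, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sim_config():
    """Simulation-study fitting settings: loose stopping, 16-iteration floor."""
    return HappiConfig(epsilon=0.0, t_max=1000, delta=0.1, min_iter=16)


@pytest.fixture
def tight_config():
    """Near-exact EM convergence for oracle comparisons."""
    return HappiConfig(epsilon=0.0, t_max=2000, delta=1e-9, min_iter=16)


@pytest.fixture
def null_dataset():
    return simulate_dataset(SimulationConfig(n=50, beta=(0.0, 0.0), seed=42))


@pytest.fixture
def effect_dataset():
    return simulate_dataset(SimulationConfig(n=60, beta=(0.0, 2.0), seed=7))
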