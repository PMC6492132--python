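import numpy as np
import pytest

from fcstates import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 4 subjects x 3 states x 6 nodes, short scans."""
    return SimulationConfig(
        n_subjects=4, n_states=3, n_nodes=6, n_timepoints=120, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, truth = simulate_dataset(small_config)
    return dataset, truth
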