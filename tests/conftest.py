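import numpy as np
import pytest

from nirscv import SimulationConfig, make_design, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def compact_config(**overrides) -> SimulationConfig:
    """A small cohort configuration used where full acquisition geometry
    would only add runtime: 16 channels, short runs."""
    defaults = dict(n_channels=16, seed=0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def compact_design(**overrides):
    """60-s runs at 10 samples/s with the standard 18 s / 12 s blocks."""
    defaults = dict(sample_rate=10.0, total_duration=60.0, task_epoch=18.0, rest_epoch=12.0)
    defaults.update(overrides)
    return make_design(**defaults)


@pytest.fixture
def compact_cohort():
    return simulate_cohort(compact_config(), compact_design())


@pytest.fixture
def noiseless_config():
    return compact_config(noise_sd=0.0, global_sd=0.0, drift_sd=0.0)
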