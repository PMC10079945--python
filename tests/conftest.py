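import numpy as np
import pytest

from spikeraster.synth import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def short_recording():
    """A 10 s noiseless-ish recording small enough for fast tests."""
    cfg = SimulationConfig(duration=10.0, snr=4.0, seed=7, n_recordings=1)
    return cfg, simulate_recording(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
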