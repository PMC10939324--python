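import numpy as np
import pytest

from reachmetrics.simulate import BlockSpec, SimulationConfig, simulate_session

#: reduced two-block protocol (baseline + one retention) for fast tests
SMALL_PROTOCOL = (
    BlockSpec("baseline", "none", 4, 1.2, 3.0),
    BlockSpec("retention", "TH", 4, 0.9, 2.0),
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_participants=2, seed=123, protocol=SMALL_PROTOCOL)


@pytest.fixture(scope="session")
def session_default(small_config):
    """One simulated participant with default noise, EMG included."""
    return simulate_session(small_config, 0)


@pytest.fixture(scope="session")
def session_noise_free(small_config):
    """Same participant with (numerically) zero position noise, no EMG."""
    import dataclasses

    cfg = dataclasses.replace(small_config, position_noise_sd=1e-15)
    return simulate_session(cfg, 0, include_emg=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
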