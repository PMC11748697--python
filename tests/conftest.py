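import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emgshift as es

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg() -> es.ProtocolConfig:
    """Protocol with full trial counts but 1 kHz / 1 s trials for speed."""
    return es.ProtocolConfig(sampling_rate=1000.0, trial_length=1.0, seed=11)


@pytest.fixture(scope="session")
def default_sp() -> es.SimulationParams:
    return es.SimulationParams(seed=11)


@pytest.fixture(scope="session")
def small_day1_features(small_cfg, default_sp):
    """Feature table of two participants, day 1, one session (small trials)."""
    return es.simulate_features(small_cfg, default_sp, participants=[1, 2],
                                days=[1], sessions=[1])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
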