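import numpy as np
import pytest

from slicephys import RippleDetectParams, RippleSimParams, TimeSeriesTrace, simulate_lfp


@pytest.fixture
def detect_params():
    return RippleDetectParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_trace(rng):
    """2 s of white noise at 10 kHz."""
    return TimeSeriesTrace(rng.standard_normal(20000), 10_000.0)


@pytest.fixture(scope="session")
def saturated_sim():
    """60 s simulated LFP at saturating SNR with its ground truth."""
    params = RippleSimParams(duration_s=60.0, event_rate_hz=0.2, snr=20.0, seed=42)
    return simulate_lfp(params)
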