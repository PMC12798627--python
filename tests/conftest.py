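import numpy as np
import pytest

from physiopipe.io import Channel
from physiopipe.simulate import (
    BREATHWORK_478,
    FREE_BREATHING,
    SimulationConfig,
    simulate_ecg,
    simulate_respiration,
    simulate_session,
)


@pytest.fixture(scope="session")
def breathwork_session():
    """One full 10-minute breathwork session with ground truth."""
    cfg = SimulationConfig(seed=11, protocol=BREATHWORK_478)
    return simulate_session(cfg, participant_id="bw")


@pytest.fixture(scope="session")
def rain_session():
    """One full 10-minute free-breathing (rain) session with ground truth."""
    cfg = SimulationConfig(seed=12, protocol=FREE_BREATHING)
    return simulate_session(cfg, participant_id="rain")


@pytest.fixture(scope="session")
def ecg_60bpm():
    """Unmodulated 60 bpm ECG and its true R-peak times."""
    cfg = SimulationConfig(seed=21, mean_hr_bpm=60.0, rr_modulation=())
    return simulate_ecg(cfg)


@pytest.fixture(scope="session")
def resp_free_15bpm():
    """Free breathing at a constant 15 breaths/min with truth onsets."""
    cfg = SimulationConfig(seed=31, protocol=FREE_BREATHING, base_breath_rate_bpm=15.0)
    return simulate_respiration(cfg)


def make_channel(samples, fs, modality="EDA", t0=0.0):
    return Channel(modality, np.asarray(samples, dtype=float), fs=fs, t0=t0)


@pytest.fixture
def channel_factory():
    return make_channel
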