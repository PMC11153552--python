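import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from luciclock import Epoch, ProtocolSchedule, Regime, TimeSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Silence the intentional "assuming 0 counts" background warning in tests.
logging.getLogger("luciclock.preprocess").setLevel(logging.ERROR)


@pytest.fixture
def study_schedule() -> ProtocolSchedule:
    """3 days 12:12 LD/CW entrainment + 4 days free run, ZT0 at t=0."""
    return ProtocolSchedule(
        zt0_recording_offset=0.0,
        epochs=[Epoch(0.0, 72.0, Regime.CYCLIC), Epoch(72.0, 168.0, Regime.FREE_RUN)],
    )


@pytest.fixture
def grid_30min():
    """7-day half-hour grid."""
    return np.arange(0.0, 168.0 + 1e-9, 0.5)


def cosine_series(
    times: np.ndarray,
    period_h: float = 24.0,
    amplitude: float = 1.0,
    mesor: float = 0.0,
    acrophase_h: float = 0.0,
    interval: float = 0.5,
) -> TimeSeries:
    """Noiseless cosinor-model series used across test modules."""
    y = mesor + amplitude * np.cos(2 * np.pi * (times - acrophase_h) / period_h)
    return TimeSeries(times, y, interval)
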