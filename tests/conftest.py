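import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def study_times():
    """The emulated harvest grid: every 2 h from 32 to 58 h, 4 replicates."""
    return np.tile(np.arange(32.0, 60.0, 2.0), 4)


@pytest.fixture
def single_rep_times():
    return np.arange(32.0, 60.0, 2.0)


def cosine(t, mesor, amplitude, phase, period=24.0):
    return mesor + amplitude * np.cos(2.0 * np.pi * (t - phase) / period)
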