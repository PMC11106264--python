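import numpy as np
import pytest

from sleepstagekit.core import RawRecording
from sleepstagekit.synthetic import (
    MovementModel,
    default_movement_model,
    default_stage_model,
    simulate_hypnogram,
    simulate_recording,
)

STAGE_NAMES = ("W", "N1", "N2", "N3", "R")


@pytest.fixture(scope="session")
def stage_model():
    return default_stage_model()


@pytest.fixture(scope="session")
def movement_model():
    return default_movement_model()


@pytest.fixture(scope="session")
def silent_movement():
    """All noise and burst parameters zero: the signal is pure gravity."""
    zeros = {s: 0.0 for s in STAGE_NAMES}
    return MovementModel(
        baseline_noise_sd_mg=dict(zeros),
        burst_rate_per_min=dict(zeros),
        burst_amplitude_sd_mg=dict(zeros),
        posture_shift_rate_per_hour=dict(zeros),
        device_noise_sd_mg=0.0,
        daytime_activity_sd_mg=0.0,
    )


@pytest.fixture(scope="session")
def short_hypnogram(stage_model):
    return simulate_hypnogram(stage_model, 20, seed=11)


@pytest.fixture(scope="session")
def gravity_recording(short_hypnogram, silent_movement):
    return simulate_recording(short_hypnogram, silent_movement, seed=5)


def constant_recording(value=(0.0, 0.0, 1.0), minutes=5.0, rate=30.0, start="2024-01-01T00:00:00"):
    n = int(round(minutes * 60 * rate))
    samples = np.tile(np.asarray(value, dtype=float), (n, 1))
    return RawRecording("const", start, rate, samples)
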