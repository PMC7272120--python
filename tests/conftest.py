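import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermocode as tc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def step_trace():
    """Default 32->42 degC ramp-hold-ramp stimulus at 1 kHz."""
    return tc.make_step_waveform(tc.StepWaveformParams(32.0, 42.0))


@pytest.fixture(scope="session")
def heat_ramp():
    """1 degC/s search ramp, 32->48 degC."""
    return tc.make_linear_ramp(tc.RampParams(32.0, 48.0, 1.0))


@pytest.fixture(scope="session")
def default_session():
    """One simulated session under default schedule/observer parameters."""
    return tc.simulate_session(tc.SessionSchedule(seed=7), tc.ObserverParams())


@pytest.fixture(scope="session")
def small_spec():
    """A small population for train-level simulations."""
    return tc.PopulationSpec(density=8.0, area=4.0, seed=11)


def constant_trace(temp, duration, sample_rate=100.0):
    times = np.linspace(0.0, duration, int(duration * sample_rate) + 1)
    return tc.TemperatureTrace(times, np.full_like(times, temp), sample_rate)
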