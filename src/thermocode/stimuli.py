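"""Thermal stimulus waveforms and temperature traces.

The behavioral and afferent experiments use two stimulus families:

* ramp-hold-ramp *steps* -- a linear ramp from a baseline temperature to a
  target (default 0.5 s), a hold phase (default 3 s) and a return ramp
  (default 0.5 s), i.e. a 4 s stimulus for the defaults;
* slow *linear ramps* at a fixed rate (1 degC/s search ramps such as
  32->48 degC or 32->12 degC).

All temperatures are degrees Celsius, all times seconds from trace start,
sample rates Hz.  Traces store the command temperature; the thermal lag of
the skin is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, OutOfRangeError

__all__ = [
    "StepWaveformParams",
    "RampParams",
    "TemperatureTrace",
    "make_step_waveform",
    "make_linear_ramp",
    "temperature_at",
    "DEFAULT_SAMPLE_RATE",
]

#: Acquisition rate of the behavioral rig emulated throughout (Hz).
DEFAULT_SAMPLE_RATE = 1000.0


@dataclass(frozen=True)
class StepWaveformParams:
    """Ramp-hold-ramp stimulus: baseline -> target -> baseline."""

    baseline_temp: float = 32.0
    target_temp: float = 42.0
    ramp_up_dur: float = 0.5
    hold_dur: float = 3.0
    ramp_down_dur: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ramp_up_dur", "hold_dur", "ramp_down_dur"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def total_duration(self) -> float:
        return self.ramp_up_dur + self.hold_dur + self.ramp_down_dur

    @property
    def amplitude(self) -> float:
        """Signed step amplitude (degC); negative for cooling steps."""
        return self.target_temp - self.baseline_temp

    def value_at(self, t):
        """Closed-form piecewise-linear temperature at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        up, hold = self.ramp_up_dur, self.hold_dur
        down_start = up + hold
        amp = self.amplitude
        out = np.full(t.shape, self.baseline_temp, dtype=float)
        if up > 0:
            m = t < up
            out[m] = self.baseline_temp + amp * t[m] / up
        m = (t >= up) & (t < down_start)
        out[m] = self.target_temp
        if self.ramp_down_dur > 0:
            m = (t >= down_start) & (t < self.total_duration)
            out[m] = self.target_temp - amp * (t[m] - down_start) / self.ramp_down_dur
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class RampParams:
    """Constant-rate linear ramp between two temperatures."""

    start_temp: float
    end_temp: float
    rate: float = 1.0  # degC/s, magnitude of dT/dt

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError(f"ramp rate must be > 0, got {self.rate}")

    @property
    def duration(self) -> float:
        return abs(self.end_temp - self.start_temp) / self.rate


@dataclass
class TemperatureTrace:
    """A sampled temperature signal with exact linear interpolation."""

    times: np.ndarray
    temps: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.size < 2:
            raise InvalidParameterError("a trace needs at least two samples")
        if self.times.size != self.temps.size:
            raise InvalidParameterError("times and temps must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("sample times must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __call__(self, t):
        return temperature_at(self, t)


def _sampled(total: float, sample_rate: float) -> np.ndarray:
    if sample_rate <= 0:
        raise InvalidParameterError(f"sample_rate must be > 0, got {sample_rate}")
    n = max(1, int(round(total * sample_rate)))
    return np.linspace(0.0, total, n + 1)


def make_step_waveform(
    params: StepWaveformParams, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> TemperatureTrace:
    """Sample a ramp-hold-ramp step; spans exactly ``params.total_duration``."""
    times = _sampled(params.total_duration, sample_rate)
    return TemperatureTrace(times, params.value_at(times), sample_rate)


def make_linear_ramp(
    params: RampParams, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> TemperatureTrace:
    """Sample a constant-rate ramp; monotone, duration |end-start|/rate."""
    times = _sampled(params.duration, sample_rate)
    temps = np.linspace(params.start_temp, params.end_temp, times.size)
    return TemperatureTrace(times, temps, sample_rate)


def temperature_at(trace: TemperatureTrace, t):
    """Linearly interpolated temperature at time(s) ``t`` within the trace span.

    Raises :class:`OutOfRangeError` for queries outside the span (with a
    1e-9 s tolerance for floating-point edge queries).
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = trace.span
    eps = 1e-9
    if np.any(t_arr < lo - eps) or np.any(t_arr > hi + eps):
        raise OutOfRangeError(f"time query outside trace span [{lo}, {hi}]")
    out = np.interp(np.clip(t_arr, lo, hi), trace.times, trace.temps)
    return out if t_arr.ndim else float(out)
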