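"""Rate models and point-process simulation of thermosensitive afferents.

Two tuning families cover the thermally driven C-fibers observed in forepaw
skin-nerve recordings:

* **Warm-excited** polymodal fibers (C-MH, warm-responsive C-MHC): silent at
  rest, recruited above an absolute temperature threshold ``t_on`` with a
  small onset discharge followed by a linear rise in firing rate
  (``gain`` Hz/degC), saturating at ``r_max``.  In the noxious range the
  slope can change: above ``noxious_accel_temp`` (44 degC) wild-type
  polymodal nociceptors accelerate dramatically (``noxious_accel``),
  while heat-transduction knockouts scale the supra-``noxious_scale_temp``
  (42 degC) slope down (``noxious_gain_scale``).  ``noxious_mode``
  "preferring" describes the rarer units whose firing rolls off linearly
  above ``rolloff_temp`` instead of rising into the noxious range.

* **Cool-driven tonic** fibers (C-MC, one C-MHC): ongoing discharge of
  0.2-6 Hz at the adaptation (background) temperature, accelerated by
  cooling (``cool_gain`` Hz/degC) and multiplicatively suppressed toward
  silence by warming (``warm_suppression_gain`` per degC).  Rates
  re-reference to the session background instantaneously: tonic discharge
  is the same at a 32 or 22 degC baseline, so these units encode the
  magnitude of temperature *change*, not absolute temperature.

Spike trains are realized as inhomogeneous Poisson processes by thinning,
with a 5 ms absolute refractory period.  Expected spike count equals the
integral of the rate along the temperature trace whenever
``rate * refractory << 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .errors import InvalidParameterError
from .stimuli import TemperatureTrace
from .utils import spawn_rng

__all__ = [
    "WarmTuning",
    "CoolTuning",
    "FiberParams",
    "fiber_rate",
    "simulate_fiber",
    "expected_spike_count",
]


@dataclass(frozen=True)
class WarmTuning:
    """Warm-excited fiber: silent at rest, monotone rate rise above t_on."""

    t_on: float  # degC, absolute recruitment threshold
    gain: float  # Hz/degC in the innocuous range
    r_max: float = 50.0  # Hz, saturation
    onset_rate: float = 2.0  # Hz discharge the moment T crosses t_on
    spont_rate: float = 0.0  # Hz ongoing rate below threshold
    noxious_mode: str = "monotonic"  # or "preferring"
    rolloff_temp: float = 46.0  # degC, only used by "preferring"
    noxious_scale_temp: float = 42.0
    noxious_gain_scale: float = 1.0  # slope multiplier above 42 degC
    noxious_accel_temp: float = 44.0
    noxious_accel: float = 3.0  # additional slope multiplier above 44 degC

    def __post_init__(self) -> None:
        if self.gain < 0 or self.r_max < 0 or self.onset_rate < 0 or self.spont_rate < 0:
            raise InvalidParameterError("warm tuning rates must be non-negative")
        if self.noxious_mode not in ("monotonic", "preferring"):
            raise InvalidParameterError(f"unknown noxious_mode {self.noxious_mode!r}")


@dataclass(frozen=True)
class CoolTuning:
    """Cool-driven fiber; tonic when ``ongoing_rate`` > 0, silent otherwise."""

    ongoing_rate: float  # Hz at the adaptation temperature
    cool_gain: float  # Hz/degC of cooling below adaptation temperature
    warm_suppression_gain: float = 0.15  # fraction of ongoing rate lost per degC warming
    adaptation_temp: Optional[float] = None  # None -> session background

    def __post_init__(self) -> None:
        if self.ongoing_rate < 0 or self.cool_gain < 0 or self.warm_suppression_gain < 0:
            raise InvalidParameterError("cool tuning rates must be non-negative")


Tuning = Union[WarmTuning, CoolTuning, None]


@dataclass(frozen=True)
class FiberParams:
    """One simulated afferent: class, conduction velocity, thermal tuning."""

    class_label: str
    cv: float  # m/s
    mech_threshold: float = 100.0  # mN; modality flag only, not analyzed further
    tuning: Tuning = None  # None -> thermally insensitive
    refractory: float = 0.005  # s, absolute
    unit_id: int = 0


def _warm_rate(tun: WarmTuning, t: np.ndarray) -> np.ndarray:
    a = tun.t_on
    t1, t2 = tun.noxious_scale_temp, tun.noxious_accel_temp
    s, acc = tun.noxious_gain_scale, tun.noxious_accel

    def ramp_part(temp):
        seg1 = np.clip(np.minimum(temp, t1) - a, 0.0, None)
        seg2 = np.clip(np.minimum(temp, t2) - max(t1, a), 0.0, None)
        seg3 = np.clip(temp - max(t2, a), 0.0, None)
        return tun.gain * (seg1 + s * seg2 + s * acc * seg3)

    r = ramp_part(t)
    if tun.noxious_mode == "preferring":
        r_roll = ramp_part(np.asarray(tun.rolloff_temp))
        over = t > tun.rolloff_temp
        r = np.where(over, np.clip(r_roll - tun.gain * (t - tun.rolloff_temp), 0.0, None), r)
    r = np.where(t >= a, r + tun.onset_rate, 0.0)
    r = np.minimum(r, tun.r_max)
    return r + tun.spont_rate


def _cool_rate(tun: CoolTuning, t: np.ndarray, background_temp: float) -> np.ndarray:
    ref = tun.adaptation_temp if tun.adaptation_temp is not None else background_temp
    delta = t - ref
    cooled = tun.ongoing_rate + tun.cool_gain * np.clip(-delta, 0.0, None)
    warmed = tun.ongoing_rate * np.clip(1.0 - tun.warm_suppression_gain * delta, 0.0, 1.0)
    return np.where(delta <= 0, cooled, warmed)


def fiber_rate(fiber: FiberParams, temp, background_temp: float = 32.0):
    """Instantaneous firing rate (Hz) at skin temperature(s) ``temp``.

    ``background_temp`` is the adapted session baseline; it anchors the
    ongoing discharge of cool-driven tonic fibers.  Never negative; a
    tuning of ``None`` (thermally insensitive fiber) gives 0 everywhere.
    """
    t = np.asarray(temp, dtype=float)
    tun = fiber.tuning
    if tun is None:
        r = np.zeros_like(t)
    elif isinstance(tun, WarmTuning):
        r = _warm_rate(tun, t)
    else:
        r = _cool_rate(tun, t, background_temp)
    return r if r.ndim else float(r)


def expected_spike_count(
    fiber: FiberParams,
    trace: TemperatureTrace,
    background_temp: float = 32.0,
    t_start: Optional[float] = None,
    t_stop: Optional[float] = None,
) -> float:
    """Integral of the rate along the trace (trapezoid on the sample grid)."""
    lo, hi = trace.span
    t0 = lo if t_start is None else t_start
    t1 = hi if t_stop is None else t_stop
    mask = (trace.times >= t0) & (trace.times <= t1)
    rates = fiber_rate(fiber, trace.temps[mask], background_temp)
    return float(np.trapezoid(rates, trace.times[mask]))


def simulate_fiber(
    fiber: FiberParams,
    trace: TemperatureTrace,
    background_temp: float = 32.0,
    seed: int = 0,
):
    """One spike train realization along ``trace`` (thinning + refractory).

    Returns an :class:`~thermocode.ephys.SpikeTrain` spanning the trace.
    """
    from .ephys import SpikeTrain  # local import to avoid a cycle

    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "fiber", fiber.unit_id)
    lo, hi = trace.span
    span = hi - lo
    rates = fiber_rate(fiber, trace.temps, background_temp)
    lam_max = float(np.max(rates))
    if lam_max <= 0:
        return SpikeTrain(fiber.unit_id, np.empty(0), recording_span=(lo, hi))
    # Bound pad covers rate variation between trace samples.
    lam_max = lam_max * 1.05 + 0.1
    n_cand = rng.poisson(lam_max * span)
    cand = np.sort(rng.uniform(lo, hi, size=n_cand))
    cand_rate = np.interp(cand, trace.times, rates)
    keep = rng.uniform(0.0, lam_max, size=n_cand) < cand_rate
    accepted = cand[keep]
    spikes = []
    last = -np.inf
    for t in accepted:
        if t - last >= fiber.refractory:
            spikes.append(t)
            last = t
    return SpikeTrain(fiber.unit_id, np.asarray(spikes), recording_span=(lo, hi))
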