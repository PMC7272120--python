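"""Synthetic go/no-go sessions: trial schedules and a stochastic observer.

The schedule interleaves stimulus and catch trials (default 50 + 50) at
randomized inter-trial intervals of 3-30 s, each trial followed by a 3.5 s
response window.  The observer emits

* baseline licks from a homogeneous Poisson process (spontaneous licking,
  the source of false alarms), and
* on each *detected* stimulus trial one stimulus-locked lick at a
  log-normal latency after onset.

Detection probability follows a Weibull psychometric function of step
amplitude A (degC):

    p(A) = guess + (1 - guess - lapse) * (1 - exp(-ln4 * (A / threshold)**slope))

so ``threshold_amp`` is the amplitude at 75% of the lapse-limited
asymptote.  Rewards are delivered at the first in-window lick of a
stimulus trial.  Everything is reproducible under the schedule seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .psychophysics import SessionLog
from .stimuli import StepWaveformParams
from .utils import spawn_rng

__all__ = [
    "SessionSchedule",
    "PsychometricParams",
    "LatencyParams",
    "ObserverParams",
    "detection_probability",
    "generate_schedule",
    "simulate_session",
]


@dataclass(frozen=True)
class SessionSchedule:
    """Trial schedule of one session."""

    n_stim_trials: int = 50
    n_catch_trials: int = 50
    iti_min: float = 3.0
    iti_max: float = 30.0
    response_window: float = 3.5
    pre_stim_lockout: float = 2.0
    stimulus: StepWaveformParams = field(default_factory=StepWaveformParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iti_min < 0 or self.iti_min > self.iti_max:
            raise InvalidParameterError("need 0 <= iti_min <= iti_max")
        if self.response_window <= 0:
            raise InvalidParameterError("response_window must be > 0")
        if self.n_stim_trials < 0 or self.n_catch_trials < 0:
            raise InvalidParameterError("trial counts must be >= 0")


@dataclass(frozen=True)
class PsychometricParams:
    threshold_amp: float = 1.0  # degC at 75% of asymptote
    slope: float = 3.0
    lapse: float = 0.02
    guess: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_amp <= 0 or self.slope <= 0:
            raise InvalidParameterError("threshold_amp and slope must be > 0")
        if not (0 <= self.lapse <= 1 and 0 <= self.guess <= 1 and self.lapse + self.guess <= 1):
            raise InvalidParameterError("lapse and guess must be probabilities summing <= 1")


@dataclass(frozen=True)
class LatencyParams:
    median: float = 0.8  # s; log-normal median of stimulus-locked licks
    spread: float = 0.4  # dimensionless sigma of log latency

    def __post_init__(self) -> None:
        if self.median <= 0 or self.spread < 0:
            raise InvalidParameterError("median must be > 0 and spread >= 0")


@dataclass(frozen=True)
class ObserverParams:
    baseline_lick_rate: float = 0.1  # Hz spontaneous licking
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    latency: LatencyParams = field(default_factory=LatencyParams)

    def __post_init__(self) -> None:
        if self.baseline_lick_rate < 0:
            raise InvalidParameterError("baseline_lick_rate must be >= 0")


def detection_probability(observer: ObserverParams, amplitude: float) -> float:
    """Weibull detection probability for a warming step of ``amplitude`` degC."""
    p = observer.psychometric
    if amplitude <= 0:
        return p.guess
    core = 1.0 - np.exp(-np.log(4.0) * (amplitude / p.threshold_amp) ** p.slope)
    return float(p.guess + (1.0 - p.guess - p.lapse) * core)


def generate_schedule(schedule: SessionSchedule, seed: Optional[int] = None) -> pd.DataFrame:
    """Randomized trial table: trial_id, type, onset_s, amplitude_c.

    Inter-onset gaps equal stimulus duration plus a uniform 3-30 s
    interval, so consecutive stimuli never overlap.  Catch trials carry a
    virtual onset and amplitude 0.
    """
    rng = spawn_rng(schedule.seed if seed is None else seed, "schedule")
    types = np.array(
        ["stimulus"] * schedule.n_stim_trials + ["catch"] * schedule.n_catch_trials
    )
    rng.shuffle(types)
    n = types.size
    stim_dur = schedule.stimulus.total_duration
    gaps = stim_dur + rng.uniform(schedule.iti_min, schedule.iti_max, size=n)
    onsets = np.cumsum(gaps)
    amp = schedule.stimulus.amplitude
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "type": types,
            "onset_s": onsets,
            "amplitude_c": np.where(types == "stimulus", amp, 0.0),
        }
    )


def simulate_session(
    schedule: SessionSchedule,
    observer: ObserverParams,
    seed: Optional[int] = None,
) -> SessionLog:
    """Simulate one behavioral session of the synthetic observer."""
    base_seed = schedule.seed if seed is None else seed
    trials = generate_schedule(schedule, seed=base_seed)
    rng = spawn_rng(base_seed, "observer")
    end = float(trials["onset_s"].iloc[-1]) + schedule.stimulus.total_duration + schedule.response_window if len(trials) else 0.0

    licks = []
    if observer.baseline_lick_rate > 0 and end > 0:
        n_base = rng.poisson(observer.baseline_lick_rate * end)
        licks.extend(rng.uniform(0.0, end, size=n_base))
    p_amp = detection_probability(observer, schedule.stimulus.amplitude)
    lat = observer.latency
    for trial in trials.itertuples(index=False):
        if trial.type != "stimulus":
            continue
        if rng.uniform() < p_amp:
            latency = rng.lognormal(mean=np.log(lat.median), sigma=lat.spread)
            licks.append(trial.onset_s + latency)
    licks = np.sort(np.asarray(licks))

    rewards = []
    for trial in trials.itertuples(index=False):
        if trial.type != "stimulus":
            continue
        w = licks[(licks > trial.onset_s) & (licks <= trial.onset_s + schedule.response_window)]
        if w.size:
            rewards.append(float(w[0]))
    meta = {
        "n_stim_trials": schedule.n_stim_trials,
        "n_catch_trials": schedule.n_catch_trials,
        "response_window": schedule.response_window,
        "pre_stim_lockout": schedule.pre_stim_lockout,
        "amplitude_c": schedule.stimulus.amplitude,
        "baseline_temp_c": schedule.stimulus.baseline_temp,
        "seed": base_seed,
    }
    return SessionLog(trials=trials, licks=licks, rewards=np.asarray(rewards), meta=meta)
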