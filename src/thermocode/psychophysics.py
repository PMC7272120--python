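"""Behavioral scoring: hits, false alarms, corrected d', latencies, PSTHs.

A go/no-go session interleaves stimulus and catch trials.  A *hit* is a
lick within the window of opportunity (default 3.5 s) after stimulus
onset; a *false alarm* is a lick within an equally long window on a catch
trial.  Sensitivity is quantified with the signal-detection index

    d' = z(h) - z(fa),

where ``z`` is the inverse of the standard normal CDF.  Extreme rates are
replaced by ``1 - 1/(2N)`` (rate 1) or ``1/(2N)`` (rate 0), with ``N`` the
number of trials of that type, so d' is always finite.  Windows are
half-open ``(onset, onset + window]``: a lick exactly at onset cannot be a
response to the stimulus.  Licks during the pre-onset lockout (default
2 s) are excluded from scoring and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidParameterError

__all__ = [
    "SessionLog",
    "SessionMetrics",
    "LickPSTH",
    "ThresholdResult",
    "score_trials",
    "corrected_rate",
    "dprime",
    "session_metrics",
    "first_lick_latencies",
    "lick_psth",
    "bootstrap_rate_difference",
    "learning_curve",
    "estimate_threshold",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 3.5  # s, window of opportunity
DEFAULT_LOCKOUT = 2.0  # s, pre-onset lockout
DEFAULT_N_BOOT = 10_000

OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")


@dataclass
class SessionLog:
    """One behavioral session: trial table plus lick and reward timestamps.

    ``trials`` columns: trial_id, type ("stimulus"/"catch"), onset_s,
    amplitude_c.  Onsets are strictly increasing; every reward coincides
    with a lick.
    """

    trials: pd.DataFrame
    licks: np.ndarray
    rewards: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.licks = np.sort(np.asarray(self.licks, dtype=float))
        self.rewards = np.sort(np.asarray(self.rewards, dtype=float))
        required = {"trial_id", "type", "onset_s", "amplitude_c"}
        missing = required - set(self.trials.columns)
        if missing:
            raise InvalidParameterError(f"trial table missing columns {sorted(missing)}")
        onsets = self.trials["onset_s"].to_numpy()
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise InvalidParameterError("trial onsets must be strictly increasing")


def score_trials(
    log: SessionLog,
    window: float = DEFAULT_WINDOW,
    lockout: float = DEFAULT_LOCKOUT,
) -> pd.DataFrame:
    """Per-trial outcomes partitioning trials into hit/miss/FA/correct rejection.

    Catch trials use a window of the same length anchored at their virtual
    onset.  Adds ``first_lick_latency_s`` (hits and false alarms only) and
    a ``lockout_lick`` flag for licks in the ``lockout`` s before onset.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    licks = log.licks
    rows = []
    for trial in log.trials.itertuples(index=False):
        onset = trial.onset_s
        in_window = licks[(licks > onset) & (licks <= onset + window)]
        responded = in_window.size > 0
        latency = float(in_window[0] - onset) if responded else np.nan
        if trial.type == "stimulus":
            outcome = "hit" if responded else "miss"
        else:
            outcome = "false_alarm" if responded else "correct_rejection"
        lockout_lick = bool(np.any((licks >= onset - lockout) & (licks < onset)))
        rows.append(
            {
                "trial_id": trial.trial_id,
                "type": trial.type,
                "onset_s": onset,
                "amplitude_c": trial.amplitude_c,
                "outcome": outcome,
                "first_lick_latency_s": latency,
                "lockout_lick": lockout_lick,
            }
        )
    return pd.DataFrame(rows)


def corrected_rate(rate: float, n: int) -> float:
    """Boundary-corrected response rate: 0 -> 1/(2N), 1 -> 1 - 1/(2N)."""
    if n < 1:
        raise InvalidParameterError("trial count must be >= 1")
    if not 0.0 <= rate <= 1.0:
        raise InvalidParameterError(f"rate must lie in [0, 1], got {rate}")
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime(h: float, fa: float, n_stim: int, n_catch: int) -> float:
    """Corrected sensitivity index z(h) - z(fa); finite for any valid input."""
    return float(
        norm.ppf(corrected_rate(h, n_stim)) - norm.ppf(corrected_rate(fa, n_catch))
    )


@dataclass
class SessionMetrics:
    """Summary of one scored session."""

    n_stim: int
    n_catch: int
    hit_rate: float
    fa_rate: float
    dprime: float
    mean_first_lick_latency: float  # s, over hit trials; NaN if no hits
    outcomes: pd.DataFrame = field(repr=False)


def session_metrics(log: SessionLog, window: float = DEFAULT_WINDOW) -> SessionMetrics:
    """Score a session and compute hit/false-alarm rates and corrected d'."""
    outcomes = score_trials(log, window=window)
    stim = outcomes[outcomes["type"] == "stimulus"]
    catch = outcomes[outcomes["type"] == "catch"]
    n_stim, n_catch = len(stim), len(catch)
    if n_stim == 0 or n_catch == 0:
        raise InvalidParameterError("session needs at least one stimulus and one catch trial")
    h = float((stim["outcome"] == "hit").mean())
    fa = float((catch["outcome"] == "false_alarm").mean())
    lat = stim.loc[stim["outcome"] == "hit", "first_lick_latency_s"]
    return SessionMetrics(
        n_stim=n_stim,
        n_catch=n_catch,
        hit_rate=h,
        fa_rate=fa,
        dprime=dprime(h, fa, n_stim, n_catch),
        mean_first_lick_latency=float(lat.mean()) if len(lat) else np.nan,
        outcomes=outcomes,
    )


def first_lick_latencies(log: SessionLog, window: float = DEFAULT_WINDOW) -> pd.Series:
    """Latency of the first in-window lick on hit trials, indexed by trial_id."""
    outcomes = score_trials(log, window=window)
    hits = outcomes[outcomes["outcome"] == "hit"]
    return pd.Series(
        hits["first_lick_latency_s"].to_numpy(), index=hits["trial_id"].to_numpy(), name="latency_s"
    )


@dataclass
class LickPSTH:
    """Histogram of first-lick times relative to trial onset."""

    bin_edges: np.ndarray
    counts_stimulus: np.ndarray
    counts_catch: np.ndarray
    normalization: str = "count"
    n_stim_trials: int = 0
    n_catch_trials: int = 0


def lick_psth(
    logs: Sequence[SessionLog],
    bin_width: float = 0.25,
    window: tuple[float, float] = (-1.0, DEFAULT_WINDOW),
) -> LickPSTH:
    """First-lick PSTH pooled over sessions, stimulus and catch separately.

    The event per trial is the first lick after onset (within ``window[1]``);
    the sum over bins equals the number of such first licks (conservation).
    Empty input gives an empty (all-zero) PSTH.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    pre, post = window
    n_bins = int(np.ceil((post - pre) / bin_width - 1e-12))
    edges = pre + bin_width * np.arange(n_bins + 1)
    counts = {"stimulus": np.zeros(n_bins), "catch": np.zeros(n_bins)}
    n_trials = {"stimulus": 0, "catch": 0}
    for log in logs:
        for trial in log.trials.itertuples(index=False):
            n_trials[trial.type] += 1
            after = log.licks[(log.licks > trial.onset_s) & (log.licks <= trial.onset_s + post)]
            if after.size == 0:
                continue
            rel = after[0] - trial.onset_s
            if edges[0] <= rel < edges[-1]:
                counts[trial.type][int((rel - edges[0]) // bin_width)] += 1
    return LickPSTH(
        bin_edges=edges,
        counts_stimulus=counts["stimulus"],
        counts_catch=counts["catch"],
        n_stim_trials=n_trials["stimulus"],
        n_catch_trials=n_trials["catch"],
    )


def bootstrap_rate_difference(
    outcomes: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    ci: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for hit rate minus false-alarm rate.

    Resamples stimulus and catch trials independently with replacement.
    """
    rng = np.random.default_rng(seed)
    hits = (outcomes.loc[outcomes["type"] == "stimulus", "outcome"] == "hit").to_numpy()
    fas = (outcomes.loc[outcomes["type"] == "catch", "outcome"] == "false_alarm").to_numpy()
    if hits.size == 0 or fas.size == 0:
        raise InvalidParameterError("need both stimulus and catch trials to bootstrap")
    h_star = rng.integers(0, hits.size, size=(n_boot, hits.size))
    f_star = rng.integers(0, fas.size, size=(n_boot, fas.size))
    diff = hits[h_star].mean(axis=1) - fas[f_star].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    return float(np.quantile(diff, alpha)), float(np.quantile(diff, 1.0 - alpha))


def learning_curve(
    logs: Sequence[SessionLog],
    window: float = DEFAULT_WINDOW,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-session hit rate, false-alarm rate, d' and bootstrap h-fa CI."""
    if len(logs) == 0:
        raise InvalidParameterError("need at least one session")
    rows = []
    for i, log in enumerate(logs):
        m = session_metrics(log, window=window)
        lo, hi = bootstrap_rate_difference(m.outcomes, n_boot=n_boot, seed=seed + i)
        rows.append(
            {
                "session": i,
                "hit_rate": m.hit_rate,
                "fa_rate": m.fa_rate,
                "dprime": m.dprime,
                "hf_diff_ci_low": lo,
                "hf_diff_ci_high": hi,
                "mean_first_lick_latency_s": m.mean_first_lick_latency,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ThresholdResult:
    """Perceptual threshold estimate over an amplitude series."""

    threshold: Optional[float]  # degC; None when no amplitude qualifies
    table: pd.DataFrame


def estimate_threshold(
    series: Sequence[tuple[float, SessionLog]],
    criterion_dprime: float = 1.0,
    window: float = DEFAULT_WINDOW,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> ThresholdResult:
    """Smallest amplitude detected better than chance.

    An amplitude qualifies when its session d' reaches ``criterion_dprime``
    and the bootstrap CI of (hit rate - false-alarm rate) excludes zero.
    The threshold is the smallest qualifying amplitude.
    """
    if len(series) < 2:
        raise InvalidParameterError("need sessions at >= 2 amplitudes")
    rows = []
    for i, (amp, log) in enumerate(series):
        m = session_metrics(log, window=window)
        lo, hi = bootstrap_rate_difference(m.outcomes, n_boot=n_boot, seed=seed + i)
        rows.append(
            {
                "amplitude_c": amp,
                "hit_rate": m.hit_rate,
                "fa_rate": m.fa_rate,
                "dprime": m.dprime,
                "hf_diff_ci_low": lo,
                "hf_diff_ci_high": hi,
                "qualifies": bool(m.dprime >= criterion_dprime and (lo > 0 or hi < 0)),
            }
        )
    table = pd.DataFrame(rows).sort_values("amplitude_c", ignore_index=True)
    qualifying = table.loc[table["qualifies"], "amplitude_c"]
    threshold = float(qualifying.min()) if len(qualifying) else None
    return ThresholdResult(threshold=threshold, table=table)
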