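"""Single-unit afferent analysis: classification, thresholds, PSTHs.

Units are classified by conduction velocity (C < 1.2 m/s, A-delta
1.2-10 m/s inclusive, A-beta > 10 m/s) and by the stimulus modalities that
evoke spikes: mechanical + heat -> MH, mechanical + heat + cold -> MHC,
mechanical + cold -> MC, cold only -> C (as in C-C).  Thermal thresholds
are read off as the temperature at the first evoked action potential, and
responses below 42 degC (warming) or above 22 degC (cooling) count as
non-noxious.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidParameterError, OutOfRangeError
from .stimuli import TemperatureTrace, temperature_at

__all__ = [
    "SpikeTrain",
    "UnitRecord",
    "SpikePSTH",
    "conduction_velocity",
    "classify_fiber",
    "thermal_threshold",
    "is_nonnoxious_responsive",
    "ongoing_activity",
    "rate_change_index",
    "spike_psth",
    "monotonicity_class",
    "ONGOING_RATE_FLOOR",
]

#: Minimum sustained rate (Hz) counted as ongoing activity; set below the
#: 0.2 Hz floor of the observed tonic-rate range.
ONGOING_RATE_FLOOR = 0.1

C_CV_MAX = 1.2  # m/s, exclusive upper bound for C-fibers
A_DELTA_CV_MAX = 10.0  # m/s, inclusive upper bound for A-delta


@dataclass
class SpikeTrain:
    """Spike timestamps (s, strictly increasing) of one unit."""

    unit_id: int
    spike_times: np.ndarray
    recording_span: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise InvalidParameterError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def count_in(self, t0: float, t1: float) -> int:
        """Spikes in the half-open window ``(t0, t1]``."""
        return int(np.sum((self.spike_times > t0) & (self.spike_times <= t1)))


@dataclass
class UnitRecord:
    """Per-unit metadata: conduction velocity, modality flags, thresholds."""

    unit_id: int
    conduction_velocity: float
    responds_mech: bool = False
    responds_heat: bool = False
    responds_cold: bool = False
    class_label: Optional[str] = None
    warm_threshold: Optional[float] = None
    cold_threshold: Optional[float] = None
    ongoing_rate: Optional[float] = None


def conduction_velocity(distance: float, latency: float) -> float:
    """Conduction velocity (m/s) from electrical-stimulation distance and latency."""
    if distance <= 0 or latency <= 0:
        raise InvalidParameterError("distance and latency must be > 0")
    return distance / latency


def classify_fiber(record: UnitRecord) -> str:
    """Class label from conduction velocity and modality response flags.

    Total over valid records: A-beta velocities fall outside the
    thermosensory scheme and are labeled ``"A-beta"``; units with no
    thermal response are ``"non-thermosensory"``; heat-only units without
    a mechanosensitive field (not observed in the reference sample) are
    labeled with suffix ``H`` for totality.
    """
    cv = record.conduction_velocity
    if cv <= 0:
        raise InvalidParameterError(f"conduction velocity must be > 0, got {cv}")
    if cv > A_DELTA_CV_MAX:
        return "A-beta"
    prefix = "C" if cv < C_CV_MAX else "A"
    heat, cold, mech = record.responds_heat, record.responds_cold, record.responds_mech
    if not heat and not cold:
        return "non-thermosensory"
    if mech:
        suffix = "M" + ("H" if heat else "") + ("C" if cold else "")
    else:
        suffix = ("H" if heat else "") + ("C" if cold else "")
    return f"{prefix}-{suffix}"


def thermal_threshold(
    train: SpikeTrain,
    trace: TemperatureTrace,
    epoch: Optional[tuple[float, float]] = None,
) -> Optional[float]:
    """Temperature (degC) at the first spike within the stimulus epoch.

    ``epoch`` defaults to the full trace span; returns ``None`` when no
    spike falls inside it.  Raises :class:`OutOfRangeError` if the epoch
    is not covered by the trace.
    """
    lo, hi = trace.span
    t0, t1 = epoch if epoch is not None else (lo, hi)
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise OutOfRangeError("stimulus epoch not covered by the temperature trace")
    in_epoch = train.spike_times[(train.spike_times >= t0) & (train.spike_times <= t1)]
    if in_epoch.size == 0:
        return None
    return float(temperature_at(trace, in_epoch[0]))


def is_nonnoxious_responsive(
    warm_threshold: Optional[float] = None, cold_threshold: Optional[float] = None
) -> bool:
    """True iff the unit spikes to innocuous temperatures (<42 warm, >22 cool)."""
    if warm_threshold is None and cold_threshold is None:
        raise InvalidParameterError("at least one thermal threshold is required")
    warm_ok = warm_threshold is not None and warm_threshold < 42.0
    cold_ok = cold_threshold is not None and cold_threshold > 22.0
    return warm_ok or cold_ok


def ongoing_activity(
    train: SpikeTrain,
    window: tuple[float, float],
    floor: float = ONGOING_RATE_FLOOR,
) -> dict:
    """Baseline rate and ongoing flag over a stimulus-free window.

    ``is_ongoing`` requires the rate to reach ``floor`` in both halves of
    the window (sustained discharge, not a burst).  Windows shorter than
    10 s give an imprecise rate and raise a warning.
    """
    t0, t1 = window
    dur = t1 - t0
    if dur <= 0:
        raise InvalidParameterError("ongoing-activity window must have positive duration")
    if dur < 10.0:
        warnings.warn("ongoing-activity window shorter than 10 s; rate estimate is noisy")
    rate = train.count_in(t0, t1) / dur
    mid = t0 + dur / 2.0
    half_rates = (train.count_in(t0, mid) / (dur / 2.0), train.count_in(mid, t1) / (dur / 2.0))
    return {"rate": rate, "is_ongoing": bool(min(half_rates) >= floor)}


def rate_change_index(
    train: SpikeTrain,
    baseline_window: tuple[float, float],
    stim_window: tuple[float, float],
) -> Optional[float]:
    """Percent firing-rate change from baseline to stimulus window.

    -100 means complete silencing.  Returns ``None`` (undefined) when the
    baseline rate is zero.  Windows must not overlap.
    """
    b0, b1 = baseline_window
    s0, s1 = stim_window
    if b1 - b0 <= 0 or s1 - s0 <= 0:
        raise InvalidParameterError("windows must have positive duration")
    if max(b0, s0) < min(b1, s1):
        raise InvalidParameterError("baseline and stimulus windows overlap")
    base = train.count_in(b0, b1) / (b1 - b0)
    if base == 0:
        return None
    stim = train.count_in(s0, s1) / (s1 - s0)
    return 100.0 * (stim - base) / base


@dataclass
class SpikePSTH:
    """Peri-stimulus time histogram of mean spike rate across sweeps."""

    bin_edges: np.ndarray  # s, relative to stimulus onset
    rates: np.ndarray  # Hz, pooled count / (n_sweeps * bin width)
    n_sweeps: int
    n_units: int = 1

    @property
    def total_spikes(self) -> float:
        widths = np.diff(self.bin_edges)
        return float(np.sum(self.rates * widths) * self.n_sweeps)


def spike_psth(
    trains: Sequence[SpikeTrain],
    onsets,
    bin_width: float,
    window: tuple[float, float],
    n_units: int = 1,
) -> SpikePSTH:
    """PSTH over repeats: each train is one sweep, aligned to its onset.

    ``onsets`` is a scalar or one onset per sweep.  Rate per bin is the
    pooled spike count divided by (number of sweeps x bin width), so
    ``sum(rate * width) * n_sweeps`` equals the total in-window spike count
    (conservation).
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    if len(trains) == 0:
        raise InvalidParameterError("at least one sweep is required")
    pre, post = window
    onsets = np.broadcast_to(np.asarray(onsets, dtype=float), (len(trains),))
    n_bins = int(np.ceil((post - pre) / bin_width - 1e-12))
    edges = pre + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for train, onset in zip(trains, onsets):
        rel = train.spike_times - onset
        rel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        counts += np.histogram(rel, bins=edges)[0]
    rates = counts / (len(trains) * bin_width)
    return SpikePSTH(edges, rates, n_sweeps=len(trains), n_units=n_units)


def monotonicity_class(temps, rates) -> str:
    """Classify a temperature tuning curve as ``monotonic`` or ``preferring``.

    ``preferring`` units peak at least 2 degC before the top of the grid
    and fall to at most half the peak rate at the hottest point; everything
    else (including flat, non-responsive curves) is ``monotonic``.
    """
    temps = np.asarray(temps, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if temps.size < 3 or temps.size != rates.size:
        raise InvalidParameterError("need >= 3 matched temperature/rate samples")
    if not np.all(np.diff(temps) > 0):
        raise InvalidParameterError("temperature grid must be increasing")
    peak = int(np.argmax(rates))
    if rates[peak] <= 0:
        return "monotonic"
    if temps[peak] <= temps[-1] - 2.0 and rates[-1] <= 0.5 * rates[peak]:
        return "preferring"
    return "monotonic"
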