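"""Dual-channel population code for warm detection.

Skin warming recruits two concurrent afferent signals:

* **pool A** (warm-excited polymodal C-fibers, silent at rest) increases
  its pooled spike count, and
* **pool B** (cool-driven C-fibers with ongoing activity) decreases its
  pooled count below the pre-stimulus baseline.

An ideal observer reads pooled spike counts in a decision window (default
1 s) after stimulus onset and in a matched pre-stimulus window.  Evidence
is ``e = pool_a_count - pool_a_baseline`` (excitation) and
``s = pool_b_baseline - pool_b_count`` (suppression).  Two combination
rules are provided:

* ``sum``: e + s (each normalized by its null-epoch standard deviation) --
  either channel alone suffices;
* ``coincidence`` (default): min(e, s) after normalization -- warm is
  reported only when excitation and suppression occur together.  This rule
  captures the observation that warm-excited input alone does not support
  warm detection, and that only warming simultaneously excites one
  population while inhibiting the other (which is why warm is never
  confused with cool).

When a channel's null-epoch variance is zero but the pool exists (e.g. a
silent excitation pool during a 22->32 degC step), normalization falls
back to raw spike-count units.  When a pool has *no fibers at all* (the
trpm8 lesion removes pool B), the coincidence statistic is degenerate and
collapses to 0: detection fails regardless of the other channel.

``model_dprime`` simulates trial-by-trial decision statistics under
stimulus and null epochs.  Pooled counts of independent Poisson fibers are
themselves Poisson with the summed intensity, so trials are drawn directly
from pooled-count distributions (population identities fixed per
experiment; spike noise resampled per trial).  The 5 ms per-fiber
refractory period is neglected here (bias of order rate x refractory).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .ephys import SpikeTrain, UnitRecord
from .fibers import FiberParams, fiber_rate
from .population import PopulationSpec, sample_population
from .psychophysics import dprime as behavioral_dprime
from .stimuli import StepWaveformParams, TemperatureTrace, make_step_waveform
from .utils import spawn_rng

__all__ = [
    "DecoderParams",
    "ChannelReadout",
    "ModelResult",
    "split_pools",
    "population_readout",
    "decision_statistic",
    "discriminate_warm_cool",
    "model_dprime",
    "lesion_experiment",
    "spatial_summation_curve",
    "informative_fiber_budget",
]


@dataclass(frozen=True)
class DecoderParams:
    """Ideal-observer configuration."""

    mode: str = "coincidence"  # or "sum"
    criterion: float = 1.0  # decision threshold on the (normalized) statistic
    window: float = 1.0  # s decision window after onset

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "coincidence"):
            raise InvalidParameterError(f"unknown decoder mode {self.mode!r}")
        if self.window <= 0:
            raise InvalidParameterError("decision window must be > 0")


@dataclass
class ChannelReadout:
    """Pooled spike counts of the two channels in matched windows."""

    pool_a_count: float
    pool_a_baseline: float
    pool_b_count: float
    pool_b_baseline: float
    window: float
    n_pool_a: int = 0
    n_pool_b: int = 0

    @property
    def excitation_evidence(self) -> float:
        return self.pool_a_count - self.pool_a_baseline

    @property
    def suppression_evidence(self) -> float:
        return self.pool_b_baseline - self.pool_b_count

    @property
    def is_empty(self) -> bool:
        return self.n_pool_a == 0 and self.n_pool_b == 0


@dataclass
class ModelResult:
    """Outcome of a simulated detection experiment."""

    genotype: str
    baseline_temp: float
    amplitude: float
    area: float
    mode: str
    predicted_dprime: float  # distribution-based (mu_stim - mu_null) / pooled sigma
    criterion_dprime: float  # from criterion-thresholded decisions
    n_trials: int
    degenerate: bool = False
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object), repr=False)
    statistic_stim: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    statistic_null: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def split_pools(records: Sequence[UnitRecord]) -> tuple[list[int], list[int]]:
    """Indices of the warm-excited pool (A) and the tonic cool-driven pool (B).

    Pool B is identified by ongoing activity; pool A by a heat response
    without ongoing activity.
    """
    idx_a = [
        i
        for i, r in enumerate(records)
        if r.responds_heat and (r.ongoing_rate is None or r.ongoing_rate == 0)
    ]
    idx_b = [i for i, r in enumerate(records) if r.ongoing_rate is not None and r.ongoing_rate > 0]
    return idx_a, idx_b


def population_readout(
    trains: Sequence[SpikeTrain],
    records: Sequence[UnitRecord],
    onset: float,
    window: float = 1.0,
) -> ChannelReadout:
    """Pooled channel counts in ``(onset, onset+window]`` and the matched
    pre-stimulus window ``(onset-window, onset]``."""
    if len(trains) != len(records):
        raise InvalidParameterError("need one spike train per unit record")
    idx_a, idx_b = split_pools(records)

    def pooled(idx, t0, t1):
        return float(sum(trains[i].count_in(t0, t1) for i in idx))

    return ChannelReadout(
        pool_a_count=pooled(idx_a, onset, onset + window),
        pool_a_baseline=pooled(idx_a, onset - window, onset),
        pool_b_count=pooled(idx_b, onset, onset + window),
        pool_b_baseline=pooled(idx_b, onset - window, onset),
        window=window,
        n_pool_a=len(idx_a),
        n_pool_b=len(idx_b),
    )


def _combine(e_norm, s_norm, mode: str):
    if mode == "sum":
        return e_norm + s_norm
    return np.minimum(e_norm, s_norm)


def decision_statistic(
    readout: ChannelReadout,
    decoder: DecoderParams,
    null_std: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Scalar decision statistic for one readout.

    ``null_std`` holds the null-epoch standard deviations of the two
    channels' evidence (estimated from null trials of the same simulation
    run); the default leaves the evidence in raw spike-count units.
    A missing pool (no fibers) makes the coincidence statistic degenerate
    (0).
    """
    sd_a = null_std[0] if null_std[0] > 0 else 1.0
    sd_b = null_std[1] if null_std[1] > 0 else 1.0
    if decoder.mode == "coincidence" and (readout.n_pool_a == 0 or readout.n_pool_b == 0):
        return 0.0
    e = readout.excitation_evidence / sd_a if readout.n_pool_a else 0.0
    s = readout.suppression_evidence / sd_b if readout.n_pool_b else 0.0
    return float(_combine(e, s, decoder.mode))


def discriminate_warm_cool(
    readout: ChannelReadout,
    decoder: DecoderParams,
    null_std: tuple[float, float] = (1.0, 1.0),
) -> str:
    """Label one readout ``warm``, ``cool`` or ``none``.

    Warm requires concurrent evidence: excitation of pool A *and*
    suppression of pool B beyond the criterion.  Cool requires pool B to
    fire above its baseline while pool A stays silent.  Only warming
    drives both channels in the warm direction, so warm and cool are never
    confused.
    """
    sd_a = null_std[0] if null_std[0] > 0 else 1.0
    sd_b = null_std[1] if null_std[1] > 0 else 1.0
    e = readout.excitation_evidence / sd_a if readout.n_pool_a else 0.0
    s = readout.suppression_evidence / sd_b if readout.n_pool_b else 0.0
    c = decoder.criterion
    if e > c and s > c:
        return "warm"
    if -s > c and e <= c:
        return "cool"
    return "none"


def _pool_intensities(
    fibers: Sequence[FiberParams],
    idx: Sequence[int],
    trace: TemperatureTrace,
    background_temp: float,
    window: float,
    baseline_temp: Optional[float] = None,
) -> tuple[float, float]:
    """Summed expected counts (stimulus window, matched baseline window).

    ``baseline_temp`` is the pre-stimulus skin temperature (defaults to the
    first trace sample, which is only correct when the trace starts at
    baseline).
    """
    mask = trace.times <= window + 1e-12
    times = trace.times[mask]
    temps = trace.temps[mask]
    if baseline_temp is None:
        baseline_temp = float(trace.temps[0])
    lam_stim = 0.0
    lam_base = 0.0
    for i in idx:
        rates = fiber_rate(fibers[i], temps, background_temp)
        lam_stim += float(np.trapezoid(rates, times))
        lam_base += float(fiber_rate(fibers[i], baseline_temp, background_temp)) * window
    return lam_stim, lam_base


def model_dprime(
    spec: PopulationSpec,
    stimulus: StepWaveformParams,
    decoder: Optional[DecoderParams] = None,
    n_trials: int = 500,
    seed: int = 0,
    background_temp: Optional[float] = None,
    sample_rate: float = 500.0,
) -> ModelResult:
    """Predicted detectability of ``stimulus`` by the dual-channel code.

    Simulates ``n_trials`` stimulus epochs and ``n_trials`` null epochs,
    forms the decision statistic per trial, and reports both the
    distribution-based d' = (mu_stim - mu_null) / pooled sigma and the d'
    of criterion-thresholded detect/no-detect decisions.
    """
    decoder = decoder or DecoderParams()
    if n_trials < 100:
        raise InvalidParameterError("n_trials must be >= 100")
    fibers, records = sample_population(spec, seed=spawn_seed_for_population(spec, seed))
    idx_a, idx_b = split_pools(records)
    trace = make_step_waveform(stimulus, sample_rate)
    background = stimulus.baseline_temp if background_temp is None else background_temp

    la_stim, la_base = _pool_intensities(
        fibers, idx_a, trace, background, decoder.window, stimulus.baseline_temp
    )
    lb_stim, lb_base = _pool_intensities(
        fibers, idx_b, trace, background, decoder.window, stimulus.baseline_temp
    )

    rng = spawn_rng(seed, "trials")

    def draw_counts(lam, size):
        return rng.poisson(lam, size=size) if lam > 0 else np.zeros(size)

    e_stim = draw_counts(la_stim, n_trials) - draw_counts(la_base, n_trials)
    e_null = draw_counts(la_base, n_trials) - draw_counts(la_base, n_trials)
    s_stim = draw_counts(lb_base, n_trials) - draw_counts(lb_stim, n_trials)
    s_null = draw_counts(lb_base, n_trials) - draw_counts(lb_base, n_trials)

    sd_a = float(np.std(e_null)) or 1.0
    sd_b = float(np.std(s_null)) or 1.0

    degenerate = len(idx_a) == 0 or len(idx_b) == 0
    if decoder.mode == "coincidence" and degenerate:
        stat_stim = np.zeros(n_trials)
        stat_null = np.zeros(n_trials)
    else:
        ea, en = e_stim / sd_a, e_null / sd_a
        sa, sn = s_stim / sd_b, s_null / sd_b
        if len(idx_a) == 0:
            ea = np.zeros(n_trials)
            en = np.zeros(n_trials)
        if len(idx_b) == 0:
            sa = np.zeros(n_trials)
            sn = np.zeros(n_trials)
        stat_stim = _combine(ea, sa, decoder.mode)
        stat_null = _combine(en, sn, decoder.mode)

    mu_s, mu_n = float(np.mean(stat_stim)), float(np.mean(stat_null))
    var_s, var_n = float(np.var(stat_stim)), float(np.var(stat_null))
    pooled = np.sqrt((var_s + var_n) / 2.0)
    dist_dprime = 0.0 if pooled == 0 else (mu_s - mu_n) / pooled

    h = float(np.mean(stat_stim > decoder.criterion))
    fa = float(np.mean(stat_null > decoder.criterion))
    crit_dprime = behavioral_dprime(h, fa, n_trials, n_trials)

    e_lab = e_stim / sd_a
    s_lab = s_stim / sd_b
    if len(idx_a) == 0:
        e_lab = np.zeros(n_trials)
    if len(idx_b) == 0:
        s_lab = np.zeros(n_trials)
    c = decoder.criterion
    labels = np.where(
        (e_lab > c) & (s_lab > c),
        "warm",
        np.where((-s_lab > c) & (e_lab <= c), "cool", "none"),
    ).astype(object)

    return ModelResult(
        genotype=spec.genotype,
        baseline_temp=stimulus.baseline_temp,
        amplitude=stimulus.amplitude,
        area=spec.area,
        mode=decoder.mode,
        predicted_dprime=float(dist_dprime),
        criterion_dprime=float(crit_dprime),
        n_trials=n_trials,
        degenerate=degenerate,
        labels=labels,
        statistic_stim=stat_stim,
        statistic_null=stat_null,
    )


def spawn_seed_for_population(spec: PopulationSpec, seed: int) -> int:
    """Child seed binding population identity to (experiment seed, genotype)."""
    from .utils import spawn_seed

    return spawn_seed(seed, "identities", spec.genotype)


def lesion_experiment(
    genotypes: Sequence[str],
    amplitudes: Sequence[float],
    decoder: Optional[DecoderParams] = None,
    spec: Optional[PopulationSpec] = None,
    baseline_temp: float = 32.0,
    n_trials: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted d' grid over genotype presets and warm-step amplitudes."""
    spec = spec or PopulationSpec()
    rows = []
    for g in genotypes:
        gspec = replace(spec, genotype=g)
        for amp in amplitudes:
            stim = StepWaveformParams(baseline_temp=baseline_temp, target_temp=baseline_temp + amp)
            res = model_dprime(gspec, stim, decoder=decoder, n_trials=n_trials, seed=seed)
            rows.append(
                {
                    "genotype": g,
                    "baseline_c": baseline_temp,
                    "amplitude_c": amp,
                    "predicted_dprime": res.predicted_dprime,
                    "criterion_dprime": res.criterion_dprime,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


def spatial_summation_curve(
    spec: PopulationSpec,
    areas: Sequence[float],
    stimulus: StepWaveformParams,
    decoder: Optional[DecoderParams] = None,
    n_trials: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted d' versus stimulated skin area (spatial summation)."""
    rows = []
    for area in areas:
        if area <= 0:
            raise InvalidParameterError("areas must be > 0")
        res = model_dprime(replace(spec, area=area), stimulus, decoder=decoder, n_trials=n_trials, seed=seed)
        rows.append({"area_mm2": area, "predicted_dprime": res.predicted_dprime})
    return pd.DataFrame(rows)


def informative_fiber_budget(
    density: float = 176.0, thermo_fraction: float = 0.36, area: float = 22.0
) -> dict:
    """How many C-fibers can carry innocuous-temperature information.

    With 176 fibers/mm^2 and ~36% thermosensitive, >60 fibers/mm^2 are
    informative; over a ~22 mm^2 contact that is >1,300 fibers changing
    their firing for a 10 degC step.
    """
    if density <= 0 or thermo_fraction <= 0 or area <= 0:
        if thermo_fraction == 0:
            return {"per_mm2": 0.0, "total": 0.0}
        raise InvalidParameterError("density, thermo_fraction and area must be positive")
    per_mm2 = density * thermo_fraction
    return {"per_mm2": per_mm2, "total": per_mm2 * area}
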