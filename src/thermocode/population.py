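"""Synthetic afferent populations and genotype lesion presets.

A population is parameterized by the C-fiber innervation density of
forepaw glabrous skin (176 fibers/mm^2, from transmission-EM fiber
counts), the fraction responsive to innocuous temperature change (~36%),
the Peltier contact area (~22 mm^2), a class mixture taken from the
skin-nerve tallies (20 C-MH, 6 C-MHC, 7 C-MC, 2 C-C of 37 thermosensitive
C-fibers, renormalized over the named classes), and the fraction of
thermosensitive fibers with ongoing activity at skin temperature (19%,
composed 5:1 of C-MC and C-MHC units).

Genotype presets implement in-silico lesions:

========================  ====================================================
wildtype                  identity
trpm8_null / pbmc_block   no tonic (ongoing) fibers; purely cool-driven
                          classes (C-MC, C-C) removed from the mix
trpv1_null                warm-excited fibers keep their innocuous gain but
                          lose the supra-44 degC acceleration
trpm2_null                cool-responsive class mass halved
tko                       trpv1:trpa1:trpm3 triple knockout: slope above
                          42 degC scaled to 10% (no noxious-heat coding),
                          cool channel intact
========================  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidParameterError
from .ephys import SpikeTrain, UnitRecord, classify_fiber
from .fibers import CoolTuning, FiberParams, WarmTuning, simulate_fiber
from .stimuli import TemperatureTrace
from .utils import spawn_rng

__all__ = [
    "PopulationSpec",
    "GenotypeEffects",
    "genotype_preset",
    "sample_population",
    "simulate_population",
    "DEFAULT_CLASS_MIX",
    "GENOTYPES",
]

#: Thermosensitive C-fiber class mixture (renormalized skin-nerve tallies).
DEFAULT_CLASS_MIX = {"C-MH": 20 / 35, "C-MHC": 6 / 35, "C-MC": 7 / 35, "C-C": 2 / 35}

#: Relative weight of each cool-capable class within the tonic subset.
TONIC_CLASS_WEIGHTS = {"C-MC": 5.0, "C-MHC": 1.0}

WARM_EXCITED_CLASSES = ("C-MH", "C-MHC", "A-MH")
COOL_ONLY_CLASSES = ("C-MC", "C-C", "A-MC")

_FLAGS = {
    # class -> (mech, heat, cold)
    "C-MH": (True, True, False),
    "C-MHC": (True, True, True),
    "C-MC": (True, False, True),
    "C-C": (False, False, True),
    "A-MH": (True, True, False),
    "A-MC": (True, False, True),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture, density and tuning ranges of a simulated afferent population."""

    density: float = 176.0  # fibers/mm^2
    thermo_fraction: float = 0.36
    area: float = 22.0  # mm^2 Peltier contact
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    ongoing_fraction: float = 0.19
    genotype: str = "wildtype"
    seed: int = 0
    # tuning ranges, sampled uniformly per fiber
    t_on_range: tuple[float, float] = (33.0, 44.0)
    gain_range: tuple[float, float] = (0.5, 2.0)
    ongoing_range: tuple[float, float] = (0.2, 6.0)
    cool_gain_range: tuple[float, float] = (0.3, 1.5)
    warm_suppression_gain: float = 0.15
    cv_range_c: tuple[float, float] = (0.3, 1.1)

    def __post_init__(self) -> None:
        if not self.class_mix:
            raise InvalidParameterError("class_mix must not be empty")
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise InvalidParameterError(f"class_mix must sum to 1, got {total}")
        if self.density <= 0 or self.area <= 0:
            raise InvalidParameterError("density and area must be > 0")
        if not 0 <= self.thermo_fraction <= 1 or not 0 <= self.ongoing_fraction <= 1:
            raise InvalidParameterError("fractions must lie in [0, 1]")

    @property
    def n_fibers(self) -> int:
        return int(round(self.density * self.area))


@dataclass(frozen=True)
class GenotypeEffects:
    """How a genotype preset modifies the generated population."""

    name: str
    ongoing_fraction_scale: float = 1.0
    removed_classes: tuple[str, ...] = ()
    cool_class_scale: float = 1.0
    noxious_accel: float = 3.0
    noxious_gain_scale: float = 1.0

    def apply_mix(self, mix: dict) -> dict:
        out = {}
        for cls, p in mix.items():
            if cls in self.removed_classes:
                continue
            if cls in ("C-MC", "C-MHC", "C-C", "A-MC"):
                p = p * self.cool_class_scale
            out[cls] = p
        total = sum(out.values())
        if total <= 0:
            raise InvalidParameterError(f"preset {self.name!r} removes every fiber class")
        return {cls: p / total for cls, p in out.items()}


GENOTYPES = {
    "wildtype": GenotypeEffects("wildtype"),
    "trpm8_null": GenotypeEffects(
        "trpm8_null", ongoing_fraction_scale=0.0, removed_classes=("C-MC", "C-C", "A-MC")
    ),
    "pbmc_block": GenotypeEffects(
        "pbmc_block", ongoing_fraction_scale=0.0, removed_classes=("C-MC", "C-C", "A-MC")
    ),
    "trpv1_null": GenotypeEffects("trpv1_null", noxious_accel=1.0),
    "trpm2_null": GenotypeEffects("trpm2_null", cool_class_scale=0.5),
    "tko": GenotypeEffects("tko", noxious_accel=1.0, noxious_gain_scale=0.1),
}


def genotype_preset(name: str) -> GenotypeEffects:
    """Lesion preset by name; wildtype is the identity modifier."""
    try:
        return GENOTYPES[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown genotype {name!r}; choose one of {sorted(GENOTYPES)}"
        ) from None


def _uniform(rng, lohi, size=None):
    return rng.uniform(lohi[0], lohi[1], size=size)


def sample_population(
    spec: PopulationSpec, seed: Optional[int] = None
) -> tuple[list[FiberParams], list[UnitRecord]]:
    """Draw fiber identities and tuning parameters (no spikes yet).

    Classes of the thermosensitive subset are multinomial draws from the
    (preset-modified) class mix; the tonic subset is then chosen among the
    cool-capable members so that overall class proportions still follow the
    mix.  Reproducible for a given ``(spec, seed)``.
    """
    effects = genotype_preset(spec.genotype)
    mix = effects.apply_mix(spec.class_mix)
    rng = spawn_rng(spec.seed if seed is None else seed, "population")

    n_total = spec.n_fibers
    if n_total < 1:
        raise InvalidParameterError("population must contain at least one fiber")
    n_thermo = int(round(spec.thermo_fraction * n_total))
    n_tonic = int(round(spec.ongoing_fraction * effects.ongoing_fraction_scale * n_thermo))

    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    labels = [classes[i] for i in rng.choice(len(classes), size=n_thermo, p=probs)]

    cool_capable = [i for i, c in enumerate(labels) if c in ("C-MC", "C-MHC")]
    n_tonic = min(n_tonic, len(cool_capable))
    tonic_idx: set[int] = set()
    if n_tonic > 0:
        w = np.array([TONIC_CLASS_WEIGHTS[labels[i]] for i in cool_capable])
        chosen = rng.choice(len(cool_capable), size=n_tonic, replace=False, p=w / w.sum())
        tonic_idx = {cool_capable[i] for i in chosen}

    fibers: list[FiberParams] = []
    records: list[UnitRecord] = []
    for uid in range(n_total):
        if uid < n_thermo:
            cls = labels[uid]
            mech, heat, cold = _FLAGS[cls]
            cv = float(_uniform(rng, spec.cv_range_c)) if cls.startswith("C") else float(
                rng.uniform(1.2, 10.0)
            )
            ongoing = None
            if uid in tonic_idx:
                ongoing = float(_uniform(rng, spec.ongoing_range))
                tuning = CoolTuning(
                    ongoing_rate=ongoing,
                    cool_gain=float(_uniform(rng, spec.cool_gain_range)),
                    warm_suppression_gain=spec.warm_suppression_gain,
                )
            elif heat:
                tuning = WarmTuning(
                    t_on=float(_uniform(rng, spec.t_on_range)),
                    gain=float(_uniform(rng, spec.gain_range)),
                    noxious_accel=effects.noxious_accel,
                    noxious_gain_scale=effects.noxious_gain_scale,
                )
            else:  # cool-excited, silent at rest
                tuning = CoolTuning(
                    ongoing_rate=0.0,
                    cool_gain=float(_uniform(rng, spec.cool_gain_range)),
                )
        else:
            cls, (mech, heat, cold) = "non-thermosensory", (True, False, False)
            cv, ongoing, tuning = float(_uniform(rng, spec.cv_range_c)), None, None
        fiber = FiberParams(
            class_label=cls,
            cv=cv,
            mech_threshold=float(rng.uniform(20.0, 400.0)) if mech else np.inf,
            tuning=tuning,
            unit_id=uid,
        )
        record = UnitRecord(
            unit_id=uid,
            conduction_velocity=cv,
            responds_mech=mech,
            responds_heat=heat,
            responds_cold=cold,
            ongoing_rate=ongoing,
        )
        record.class_label = classify_fiber(record)
        fibers.append(fiber)
        records.append(record)
    return fibers, records


def simulate_population(
    spec: PopulationSpec,
    trace: TemperatureTrace,
    background_temp: float = 32.0,
    seed: Optional[int] = None,
) -> tuple[list[SpikeTrain], list[UnitRecord]]:
    """Sample a population and realize one spike train per fiber along ``trace``."""
    base_seed = spec.seed if seed is None else seed
    fibers, records = sample_population(spec, seed=base_seed)
    rng = spawn_rng(base_seed, "spikes")
    trains = [
        simulate_fiber(f, trace, background_temp=background_temp, seed=rng) for f in fibers
    ]
    return trains, records
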