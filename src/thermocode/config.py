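"""YAML configuration: defaults, loading, and dataclass builders.

A config file holds the sections ``stimulus``, ``schedule``, ``observer``,
``population``, ``decoder`` and ``seed``; omitted keys fall back to the
package defaults below, which encode the reference experimental
conditions (32->42 degC step, 50+50 trials, 3-30 s ITIs, 176 fibers/mm^2
over 22 mm^2, coincidence decoder with a 1 s window).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .encoding import DecoderParams
from .errors import FormatError
from .observer import LatencyParams, ObserverParams, PsychometricParams, SessionSchedule
from .population import PopulationSpec
from .stimuli import StepWaveformParams

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "stimulus_from_config",
    "schedule_from_config",
    "observer_from_config",
    "population_from_config",
    "decoder_from_config",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stimulus": {
        "baseline_temp": 32.0,
        "target_temp": 42.0,
        "ramp_up_dur": 0.5,
        "hold_dur": 3.0,
        "ramp_down_dur": 0.5,
    },
    "schedule": {
        "n_stim_trials": 50,
        "n_catch_trials": 50,
        "iti_min": 3.0,
        "iti_max": 30.0,
        "response_window": 3.5,
        "pre_stim_lockout": 2.0,
    },
    "observer": {
        "baseline_lick_rate": 0.1,
        "psychometric": {"threshold_amp": 1.0, "slope": 3.0, "lapse": 0.02, "guess": 0.0},
        "latency": {"median": 0.8, "spread": 0.4},
    },
    "population": {
        "density": 176.0,
        "thermo_fraction": 0.36,
        "area": 22.0,
        "ongoing_fraction": 0.19,
        "genotype": "wildtype",
    },
    "decoder": {"mode": "coincidence", "criterion": 1.0, "window": 1.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults, deep-merged with the YAML file at ``path`` when given."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    return _merge(DEFAULT_CONFIG, raw)


def stimulus_from_config(config: dict) -> StepWaveformParams:
    return StepWaveformParams(**config["stimulus"])


def schedule_from_config(config: dict) -> SessionSchedule:
    return SessionSchedule(
        stimulus=stimulus_from_config(config),
        seed=int(config.get("seed", 0)),
        **config["schedule"],
    )


def observer_from_config(config: dict) -> ObserverParams:
    obs = config["observer"]
    return ObserverParams(
        baseline_lick_rate=obs["baseline_lick_rate"],
        psychometric=PsychometricParams(**obs["psychometric"]),
        latency=LatencyParams(**obs["latency"]),
    )


def population_from_config(config: dict) -> PopulationSpec:
    return PopulationSpec(seed=int(config.get("seed", 0)), **config["population"])


def decoder_from_config(config: dict) -> DecoderParams:
    return DecoderParams(**config["decoder"])
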