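"""Plain-text file formats: trace CSV, session CSV, spikes CSV, units JSON.

All files are comma-separated UTF-8 with a header row and '.' decimals;
metadata and manifests are JSON.  Round trips are lossless to 1e-6.

=============  =========================================================
trace CSV      time_s,temp_c
session CSV    time_s,event,trial_id,amplitude_c with events
               stimulus_onset / catch_onset / lick / reward
spikes CSV     unit_id,spike_time_s
units JSON     list of UnitRecord fields
=============  =========================================================
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .ephys import SpikeTrain, UnitRecord
from .psychophysics import SessionLog
from .stimuli import TemperatureTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_session",
    "write_session",
    "read_spikes",
    "write_spikes",
    "read_units",
    "write_units",
    "write_manifest",
]


def write_trace(path, trace: TemperatureTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "temp_c": trace.temps}).to_csv(path, index=False)


def read_trace(path, sample_rate: float | None = None) -> TemperatureTrace:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"unreadable trace file {path}: {exc}") from exc
    for col in ("time_s", "temp_c"):
        if col not in df.columns:
            raise FormatError(f"trace file {path} missing column {col!r}")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2 or not np.all(np.diff(times) > 0):
        raise FormatError(f"trace file {path}: times must be strictly increasing (>= 2 samples)")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(times)))
    return TemperatureTrace(times, df["temp_c"].to_numpy(dtype=float), sample_rate)


def write_session(path, log: SessionLog, manifest_path=None) -> None:
    rows = []
    for t in log.trials.itertuples(index=False):
        event = "stimulus_onset" if t.type == "stimulus" else "catch_onset"
        rows.append((t.onset_s, event, t.trial_id, t.amplitude_c))
    rows.extend((t, "lick", -1, np.nan) for t in log.licks)
    rows.extend((t, "reward", -1, np.nan) for t in log.rewards)
    df = pd.DataFrame(rows, columns=["time_s", "event", "trial_id", "amplitude_c"])
    df.sort_values(["time_s", "event"], ignore_index=True).to_csv(path, index=False)
    if manifest_path is not None:
        write_manifest(manifest_path, log.meta)


def read_session(path, meta: dict | None = None) -> SessionLog:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"unreadable session file {path}: {exc}") from exc
    for col in ("time_s", "event", "trial_id"):
        if col not in df.columns:
            raise FormatError(f"session file {path} missing column {col!r}")
    onsets = df[df["event"].isin(["stimulus_onset", "catch_onset"])].sort_values("time_s")
    if "amplitude_c" not in df.columns:
        raise FormatError(f"session file {path} missing column 'amplitude_c'")
    trials = pd.DataFrame(
        {
            "trial_id": onsets["trial_id"].to_numpy(dtype=int),
            "type": np.where(onsets["event"] == "stimulus_onset", "stimulus", "catch"),
            "onset_s": onsets["time_s"].to_numpy(dtype=float),
            "amplitude_c": onsets["amplitude_c"].to_numpy(dtype=float),
        }
    )
    licks = df.loc[df["event"] == "lick", "time_s"].to_numpy(dtype=float)
    rewards = df.loc[df["event"] == "reward", "time_s"].to_numpy(dtype=float)
    return SessionLog(trials=trials, licks=licks, rewards=rewards, meta=meta or {})


def write_spikes(path, trains: Sequence[SpikeTrain]) -> None:
    rows = [(tr.unit_id, t) for tr in trains for t in tr.spike_times]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(path, index=False)


def read_spikes(path, recording_span=(0.0, 0.0)) -> list[SpikeTrain]:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"unreadable spikes file {path}: {exc}") from exc
    for col in ("unit_id", "spike_time_s"):
        if col not in df.columns:
            raise FormatError(f"spikes file {path} missing column {col!r}")
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(int(uid), np.sort(grp["spike_time_s"].to_numpy(dtype=float)), recording_span)
        )
    return trains


def write_units(path, records: Sequence[UnitRecord]) -> None:
    payload = [dataclasses.asdict(r) for r in records]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_units(path) -> list[UnitRecord]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable units file {path}: {exc}") from exc
    return [UnitRecord(**item) for item in payload]


def write_manifest(path, config: dict) -> None:
    """Full-configuration manifest, for exact re-runs."""
    Path(path).write_text(json.dumps(config, indent=1, default=str))
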