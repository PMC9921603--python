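"""CSV/JSON readers and writers for trials, parameters and results.

Angles are stored in degrees in files (goniometer convention) and converted
to radians at this boundary; everything downstream works in radians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EMGTrial, MVCReference
from .errors import SchemaError

__all__ = ["TrialRecord", "read_trial_csv", "write_trial_csv", "read_mvc",
           "write_params_json", "read_params_json"]

TRIAL_COLUMNS = ("time", "emg_ag", "emg_ant", "angle_deg")


@dataclass
class TrialRecord:
    """A trial file: EMG channels plus the goniometer angle."""

    trial: EMGTrial
    angle: np.ndarray       # rad
    angle_deg: np.ndarray   # as stored

    @property
    def time(self) -> np.ndarray:
        return self.trial.time


def read_trial_csv(path: str | Path, kind: str = "envelope") -> TrialRecord:
    """Read and validate a trial CSV (columns ``time, emg_ag, emg_ant, angle_deg``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for col in TRIAL_COLUMNS:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            raise SchemaError(f"{path}: non-finite value in column {col!r} at row {bad[0]}")
    t = df["time"].to_numpy(dtype=float)
    non_mono = np.flatnonzero(np.diff(t) <= 0)
    if non_mono.size:
        raise SchemaError(f"{path}: time not strictly increasing at row {non_mono[0] + 1}")
    fs = 1.0 / float(np.median(np.diff(t)))
    trial = EMGTrial(time=t, emg_agonist=df["emg_ag"].to_numpy(dtype=float),
                     emg_antagonist=df["emg_ant"].to_numpy(dtype=float), fs=fs, kind=kind)
    angle_deg = df["angle_deg"].to_numpy(dtype=float)
    return TrialRecord(trial=trial, angle=np.radians(angle_deg), angle_deg=angle_deg)


def write_trial_csv(path: str | Path, time, emg_ag, emg_ant, angle_deg) -> None:
    pd.DataFrame({"time": time, "emg_ag": emg_ag, "emg_ant": emg_ant,
                  "angle_deg": angle_deg}).to_csv(path, index=False)


def read_mvc(path: str | Path) -> MVCReference:
    """MVC reference from CSV (columns ``mvc_ag, mvc_ant``) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        d = json.loads(path.read_text())
        return MVCReference(float(d["mvc_ag"]), float(d["mvc_ant"]))
    df = pd.read_csv(path)
    if not {"mvc_ag", "mvc_ant"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns mvc_ag, mvc_ant")
    return MVCReference(float(df["mvc_ag"].iloc[0]), float(df["mvc_ant"].iloc[0]))


def write_params_json(path: str | Path, vector, extra: dict | None = None) -> None:
    from .parameters import PARAM_NAMES

    d = {"parameters": dict(zip(PARAM_NAMES, (float(v) for v in vector)))}
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def read_params_json(path: str | Path) -> np.ndarray:
    from .parameters import PARAM_NAMES

    d = json.loads(Path(path).read_text())
    params = d["parameters"] if "parameters" in d else d
    try:
        return np.array([float(params[n]) for n in PARAM_NAMES])
    except KeyError as exc:
        raise SchemaError(f"{path}: missing parameter {exc}") from exc
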