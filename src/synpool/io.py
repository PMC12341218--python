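"""CSV and JSON readers/writers with a fixed unit convention.

All CSVs are RFC-4180 with a header row and '.' decimal separator.  Units
are fixed across the package: time in seconds, rates in 1/s, concentrations
in uM, amplitudes in pA, fluorescence in arbitrary units.  JSON reports are
written with sorted keys so identical inputs produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import Trajectory
from .observables import CaTrace, DoseResponseData, EventTrain, PHluorinTrace
from .scenario import FluxSeries

__all__ = [
    "write_trajectory",
    "write_flux",
    "write_events",
    "read_events",
    "write_trace",
    "read_phluorin_trace",
    "read_ca_trace",
    "write_dose_response",
    "read_dose_response",
    "write_json",
    "read_json",
    "sha256_file",
]


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the offending file, pandas gives the line
        raise ValueError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    _write_csv(traj.to_frame(), path)


def write_flux(fs: FluxSeries, path: str | Path) -> None:
    _write_csv(pd.DataFrame({"time_s": fs.times, "flux_per_s": fs.flux}), path)


def write_events(train: EventTrain, path: str | Path) -> None:
    cols = {"time_s": train.times}
    if train.amplitudes is not None:
        cols["amplitude_pA"] = train.amplitudes
    _write_csv(pd.DataFrame(cols), path)


def read_events(path: str | Path, duration: float) -> EventTrain:
    df = _read_csv(path, ("time_s",))
    amps = df["amplitude_pA"].to_numpy() if "amplitude_pA" in df.columns else None
    return EventTrain(times=df["time_s"].to_numpy(), duration=duration, amplitudes=amps)


def write_trace(times: np.ndarray, values: np.ndarray, path: str | Path, value_col: str = "value") -> None:
    _write_csv(pd.DataFrame({"time_s": times, value_col: values}), path)


def read_phluorin_trace(path: str | Path) -> PHluorinTrace:
    df = _read_csv(path, ("time_s", "value"))
    return PHluorinTrace(times=df["time_s"].to_numpy(), fluorescence=df["value"].to_numpy())


def read_ca_trace(path: str | Path, stim_time: float) -> CaTrace:
    df = _read_csv(path, ("time_s", "value"))
    return CaTrace(times=df["time_s"].to_numpy(), values=df["value"].to_numpy(), stim_time=stim_time)


def write_dose_response(data: DoseResponseData, path: str | Path) -> None:
    _write_csv(
        pd.DataFrame({"concentration_uM": data.concentrations_um, "response": data.responses}),
        path,
    )


def read_dose_response(path: str | Path) -> DoseResponseData:
    df = _read_csv(path, ("concentration_uM", "response"))
    return DoseResponseData(
        concentrations_um=df["concentration_uM"].to_numpy(),
        responses=df["response"].to_numpy(),
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
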