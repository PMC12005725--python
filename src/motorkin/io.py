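"""Readers and writers for the package's delimited-text formats.

All files are comma-delimited with a required header and decimal points;
headers carry units.  Floats are written with Python's shortest
round-tripping representation so ``read(write(x)) == x`` exactly.

Formats
-------
trajectory CSV   : frame, t_s, on_nm, off_nm
FRET CSV         : t_s, donor, acceptor
stopped-flow CSV : t_s, signal
dwell CSV        : state, start_frame, end_frame, duration_s, censored,
                   origin_label, mean_on_nm, mean_off_nm
segmentation JSON: run-length-encoded labels, transitions, dwells, params,
                   noise floor
ground-truth JSON: simulator events, labels (RLE), parameters, seed
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .fret import FRETTrace
from .segmentation import (
    Dwell,
    NoiseFloor,
    SegmentationParams,
    StateSegmentation,
    Trajectory2D,
)
from .stoppedflow import Trace

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv",
    "write_fret_csv", "read_fret_csv",
    "write_trace_csv", "read_trace_csv",
    "write_dwell_csv", "read_dwell_csv",
    "write_segmentation_json", "read_segmentation_json",
    "write_ground_truth_json", "read_ground_truth_json",
    "write_rate_table_csv", "write_rate_table_json",
    "read_conditions_csv",
]

TRAJ_COLUMNS = ["frame", "t_s", "on_nm", "off_nm"]
FRET_COLUMNS = ["t_s", "donor", "acceptor"]
TRACE_COLUMNS = ["t_s", "signal"]
DWELL_COLUMNS = ["state", "start_frame", "end_frame", "duration_s", "censored",
                 "origin_label", "mean_on_nm", "mean_off_nm"]
CONDITIONS_COLUMNS = ["file", "ligand_conc_uM", "kind", "construct", "condition"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        # round_trip float parsing so read(write(x)) == x exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises many flavors
        raise ParseError(f"{path}: could not parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}; "
                         f"found {list(df.columns)}")
    return df


def _check_monotonic_time(df: pd.DataFrame, col: str, path) -> None:
    t = df[col].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        # offending data row is bad[0]+1; +1 for 1-based, +1 for the header
        raise ParseError(
            f"{path}: non-monotonic {col} at line {int(bad[0]) + 3} "
            f"({t[bad[0] + 1]!r} after {t[bad[0]]!r})"
        )


# -- trajectory --------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory2D, path) -> None:
    pd.DataFrame({
        "frame": traj.frame, "t_s": traj.t,
        "on_nm": traj.on_axis, "off_nm": traj.off_axis,
    }).to_csv(path, index=False)


def read_trajectory_csv(path, frame_rate: float | None = None) -> Trajectory2D:
    df = _read_csv(path, TRAJ_COLUMNS)
    _check_monotonic_time(df, "t_s", path)
    t = df["t_s"].to_numpy(float)
    frame = df["frame"].to_numpy(np.int64)
    if frame_rate is None:
        if len(t) < 2:
            raise ParseError(f"{path}: cannot infer frame rate from < 2 rows")
        frame_rate = float((frame[-1] - frame[0]) / (t[-1] - t[0]))
    try:
        return Trajectory2D(frame, t, df["on_nm"].to_numpy(float),
                            df["off_nm"].to_numpy(float), frame_rate)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


# -- FRET --------------------------------------------------------------------

def write_fret_csv(trace: FRETTrace, path) -> None:
    pd.DataFrame({
        "t_s": trace.t, "donor": trace.donor, "acceptor": trace.acceptor,
    }).to_csv(path, index=False)


def read_fret_csv(
    path,
    frame_interval: float | None = None,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
) -> FRETTrace:
    df = _read_csv(path, FRET_COLUMNS)
    _check_monotonic_time(df, "t_s", path)
    t = df["t_s"].to_numpy(float)
    if frame_interval is None:
        if len(t) < 2:
            raise ParseError(f"{path}: cannot infer frame interval from < 2 rows")
        frame_interval = float(np.median(np.diff(t)))
    return FRETTrace(t, df["donor"].to_numpy(float), df["acceptor"].to_numpy(float),
                     frame_interval, background_donor, background_acceptor)


# -- stopped flow ------------------------------------------------------------

def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame({"t_s": trace.t, "signal": trace.y}).to_csv(path, index=False)


def read_trace_csv(path, kind: str = "fluorescence",
                   ligand_conc: float = math.nan) -> Trace:
    df = _read_csv(path, TRACE_COLUMNS)
    _check_monotonic_time(df, "t_s", path)
    return Trace(df["t_s"].to_numpy(float), df["signal"].to_numpy(float),
                 kind=kind, ligand_conc=ligand_conc)


def read_conditions_csv(path) -> pd.DataFrame:
    """Conditions table mapping trace files to concentrations/constructs."""
    return _read_csv(path, CONDITIONS_COLUMNS)


# -- dwells ------------------------------------------------------------------

def write_dwell_csv(dwells: pd.DataFrame, path) -> None:
    missing = [c for c in DWELL_COLUMNS if c not in dwells.columns]
    if missing:
        raise ParseError(f"dwell table missing columns {missing}")
    dwells[DWELL_COLUMNS].to_csv(path, index=False)


def read_dwell_csv(path) -> pd.DataFrame:
    df = _read_csv(path, DWELL_COLUMNS)
    df["censored"] = df["censored"].astype(bool)
    df["origin_label"] = df["origin_label"].fillna("")
    return df


# -- segmentation JSON -------------------------------------------------------

def _rle(labels: np.ndarray) -> list[list[int]]:
    out = []
    arr = np.asarray(labels)
    if len(arr) == 0:
        return out
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    for s, e in zip(starts, ends):
        out.append([int(arr[s]), int(e - s)])
    return out


def _unrle(pairs: list[list[int]]) -> np.ndarray:
    if not pairs:
        return np.zeros(0, np.int8)
    return np.concatenate([np.full(count, code, np.int8) for code, count in pairs])


def write_segmentation_json(seg: StateSegmentation, path) -> None:
    doc = {
        "frame_rate": seg.frame_rate,
        "labels_rle": _rle(seg.labels),
        "transitions": [[int(f), d] for f, d in seg.transitions],
        "dwells": [dataclasses.asdict(d) for d in seg.dwells],
        "merged_groups": [list(g) for g in seg.merged_groups],
        "noise_floor": (dataclasses.asdict(seg.noise_floor)
                        if seg.noise_floor else None),
        "params": (dataclasses.asdict(seg.params) if seg.params else None),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_segmentation_json(path) -> StateSegmentation:
    doc = json.loads(Path(path).read_text())
    return StateSegmentation(
        labels=_unrle(doc["labels_rle"]),
        frame_rate=doc["frame_rate"],
        transitions=[(int(f), d) for f, d in doc["transitions"]],
        dwells=[Dwell(**d) for d in doc["dwells"]],
        merged_groups=[tuple(g) for g in doc["merged_groups"]],
        noise_floor=(NoiseFloor(**doc["noise_floor"])
                     if doc.get("noise_floor") else None),
        params=(SegmentationParams(**doc["params"]) if doc.get("params") else None),
    )


# -- ground truth ------------------------------------------------------------

def write_ground_truth_json(path, *, parameters: dict, seed: int | None = None,
                            events: list | None = None,
                            labels: np.ndarray | None = None) -> None:
    doc = {
        "parameters": parameters,
        "seed": seed,
        "events": events,
        "labels_rle": _rle(labels) if labels is not None else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1, default=_json_default))


def read_ground_truth_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("labels_rle") is not None:
        doc["labels"] = _unrle(doc["labels_rle"])
    return doc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# -- rate tables -------------------------------------------------------------

def write_rate_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_rate_table_json(table: pd.DataFrame, path) -> None:
    records = table.where(pd.notna(table), None).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1, default=_json_default))
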