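"""CSV formats, run manifests, and config-file round-tripping.

All files are plain CSV with a mandatory header row and dot decimal
separator; timestamps are seconds from the experiment start.  One file per
reactor; multi-reactor runs are directories of per-reactor files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationCurve
from .containers import CumulativeVolumeTrace, EventLog, PressureTrace, ProductionRate

__all__ = [
    "read_pressure_log",
    "write_pressure_log",
    "read_event_log",
    "write_event_log",
    "write_volume",
    "read_volume",
    "write_rate_summary",
    "write_calibration_curve",
    "read_calibration_curve",
    "RunManifest",
]

PRESSURE_COLUMNS = ("time_s", "reactor_id", "pressure_bar")
EVENT_COLUMNS = ("time_s", "reactor_id", "event_type", "value")


def _check_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.isna() & frame[column].notna() | frame[column].isna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 1  # 1-based data row
        raise ValueError(
            f"{path}: non-numeric {column} {frame[column].iloc[row - 1]!r} "
            f"at data row {row}"
        )
    return values.to_numpy(dtype=float)


def read_pressure_log(path) -> PressureTrace:
    """Read a pressure log CSV (time_s, reactor_id, pressure_bar[, flag])."""
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_columns(frame, PRESSURE_COLUMNS, path)
    time_s = _numeric(frame, "time_s", path)
    pressure = _numeric(frame, "pressure_bar", path)
    diffs = np.diff(time_s)
    if len(diffs) and np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 2
        raise ValueError(f"{path}: time regression at data row {row}")
    reactor_id = str(frame["reactor_id"].iloc[0]) if len(frame) else "R1"
    flags = frame["flag"].to_numpy(dtype=object) if "flag" in frame.columns else None
    return PressureTrace(time_s, pressure, reactor_id, flags)


def write_pressure_log(trace: PressureTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_event_log(path) -> EventLog:
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_columns(frame, EVENT_COLUMNS, path)
    _numeric(frame, "time_s", path)
    return EventLog.from_frame(frame)


def write_event_log(events: EventLog, path) -> None:
    events.to_frame().to_csv(path, index=False)


def write_volume(volume: CumulativeVolumeTrace, path) -> None:
    volume.to_frame().to_csv(path, index=False)


def read_volume(path, reactor_id: str = "R1") -> CumulativeVolumeTrace:
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_columns(frame, ("time_d", "volume_mL_STP"), path)
    flags = frame["flag"].to_numpy(dtype=object) if "flag" in frame.columns else None
    return CumulativeVolumeTrace(
        time_d=frame["time_d"].to_numpy(dtype=float),
        volume_mL_STP=frame["volume_mL_STP"].to_numpy(dtype=float),
        reactor_id=reactor_id,
        flags=flags,
    )


def write_rate_summary(rates: dict[str, ProductionRate], path) -> None:
    """Rate table: one row per reactor with the regression quartet."""
    rows = [
        {
            "reactor_id": rid,
            "slope_mL_d": r.slope_mL_d,
            "r2": r.r2,
            "se_mL_d": r.se_slope_mL_d,
            "n_points": r.n_points,
        }
        for rid, r in rates.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_calibration_curve(curve: CalibrationCurve, path) -> None:
    """Store a calibration curve as a flat TOML fragment."""
    d = curve.to_dict()
    lines = ["[calibration]"]
    for k, v in d.items():
        lines.append(f'{k} = "{v}"' if isinstance(v, str) else f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration_curve(path) -> CalibrationCurve:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return CalibrationCurve.from_dict(data["calibration"])


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to re-run it bit-identically."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    tool_version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
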