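"""Linear calibration of peristaltic pumps and pressure sensors.

Pumps are calibrated by dispensing water for a fixed time at different
commanded velocities and weighing the result (response = mL per run);
pressure sensors by imposing reference pressures and comparing readings.
Both behave linearly over the operating range, so a straight line —
optionally constrained through the origin for pumps, since zero velocity
dispenses zero — captures the response.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "apply_calibration",
    "invert_calibration",
]


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n_points: int
    kind: str = "pump"  # pump | pressure_sensor

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2={self.r2} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(**{k: d[k] for k in ("slope", "intercept", "r2",
                                        "residual_sd", "n_points", "kind")})


def fit_calibration(
    points: Iterable[Sequence[float]],
    kind: str = "pump",
    through_origin: bool = False,
) -> CalibrationCurve:
    """Least-squares line through (command, response) calibration points.

    ``through_origin`` constrains the intercept to zero (a pump at zero
    velocity dispenses zero); otherwise both slope and intercept are free,
    the default for sensors.  Needs at least two distinct command values.
    The fit only depends on the set of points, not their order.
    """
    if kind not in ("pump", "pressure_sensor"):
        raise ValueError(f"unknown calibration kind {kind!r}")
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (command, response) pairs")
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct command values to calibrate")

    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        xm, ym = x.mean(), y.mean()
        sxx = np.dot(x - xm, x - xm)
        slope = float(np.dot(x - xm, y - ym) / sxx)
        intercept = float(ym - slope * xm)

    resid = y - (slope * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    if ss_tot == 0.0:
        r2 = 0.0  # flat response carries no explanatory power
    else:
        r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    dof = n - (1 if through_origin else 2)
    residual_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    return CalibrationCurve(slope, intercept, r2, residual_sd, n, kind)


def apply_calibration(curve: CalibrationCurve, command: float) -> float:
    """Predicted response at a commanded value."""
    return curve.slope * command + curve.intercept


def invert_calibration(curve: CalibrationCurve, response: float) -> float:
    """Commanded value producing a desired response (needs slope ≠ 0)."""
    if curve.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration curve")
    return (response - curve.intercept) / curve.slope
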