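"""Motor-axis calibration: microstep/degree conversions and the linear
regression of dial readings against microstep counts.

The motorised axes are driven by stepper motors through gear sets; the
effective degrees-per-microstep of each axis is calibrated by rotating
the axis through its range, reading a Vernier dial (5 arcmin resolution)
at roughly equal intervals, and regressing dial angle on microstep count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AxisCalibration",
    "degrees_per_microstep",
    "arcmin_to_degrees",
    "fit_axis_calibration",
    "angle_to_microsteps",
    "microsteps_to_angle",
]


@dataclass(frozen=True)
class AxisCalibration:
    """Linear axis model: dial_degrees = slope * microsteps + intercept."""

    slope: float  # degrees per microstep
    intercept: float  # degrees
    r_squared: float
    n_points: int

    @property
    def valid(self) -> bool:
        """An axis with zero slope does not move the dial: invalid."""
        return self.slope != 0.0 and self.n_points >= 2


def degrees_per_microstep(microsteps_per_rev: int) -> float:
    """Angular resolution of a stepper axis: 360 / microsteps-per-revolution.

    E.g. 51,200 microsteps per full turn give 0.00703125 degrees/microstep.
    """
    if microsteps_per_rev <= 0:
        raise ValueError("microsteps_per_rev must be positive")
    return 360.0 / microsteps_per_rev


def arcmin_to_degrees(arcmin: float) -> float:
    """Arcminutes to degrees (1 degree = 60 arcmin)."""
    if not math.isfinite(arcmin):
        raise ValueError("arcmin must be finite")
    return arcmin / 60.0


def fit_axis_calibration(table) -> AxisCalibration:
    """Ordinary-least-squares line through (microsteps, dial degrees) pairs.

    ``table`` is a sequence of (microstep count, dial reading in degrees).
    Requires at least two distinct microstep values.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("table must be a sequence of (microsteps, degrees) pairs")
    steps, dial = arr[:, 0], arr[:, 1]
    if len(np.unique(steps)) < 2:
        raise ValueError("calibration needs at least 2 distinct microstep values")
    res = stats.linregress(steps, dial)
    r2 = float(res.rvalue**2)
    if not math.isfinite(r2):
        r2 = 0.0  # constant dial readings: no explainable variance
    return AxisCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(steps),
    )


def angle_to_microsteps(angle_deg: float, cal: AxisCalibration) -> int:
    """Microstep count commanding the given dial angle, rounded to the
    nearest integer (ties rounded away from zero)."""
    if cal.slope == 0.0:
        raise ValueError("invalid axis calibration: zero slope")
    x = (angle_deg - cal.intercept) / cal.slope
    return int(math.floor(abs(x) + 0.5) * math.copysign(1.0, x))


def microsteps_to_angle(microsteps: int, cal: AxisCalibration) -> float:
    """Dial angle (degrees) reached by a microstep count."""
    return cal.slope * microsteps + cal.intercept
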