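"""Forward and inverse kinematics of a three-axis ultramicrotome.

The machine has three rotational degrees of freedom: sample tilt
(``theta_T``, about World x), sample rotation (``theta_R``, about the
tilted holder's y axis), and knife tilt (``theta_K``, about World z).
World x is the east-west knife translation, y the north-south cutting
feed, and z vertical.

A targeting run is parameterised by four constant angles: the initial
sample tilt and knife tilt at the moment the knife is manually aligned to
the block face (``theta_IT``, ``theta_IK``; sample rotation is defined as
zero there), and the target offsets (``theta_to``, ``theta_tr``) measured
from the micro-CT annotations.

The orientation of the target plane for machine angles (theta_T, theta_R)
is the rotation

    F = Rx(theta_T) Ry(theta_R) Rx(-theta_IT) Rz(theta_IK)
        Rz(theta_to) Rx(theta_tr)

whose y column is the target-plane normal in World coordinates.  The cut
is achievable when that normal is horizontal — ``(F yhat) . zhat = 0`` —
which yields a one-parameter family of solutions: for every sample
rotation there is a closed-form sample tilt and a corresponding signed
knife angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import TargetOffsets
from .geometry import Rotation3, rotation_matrix

__all__ = [
    "InitialAlignment",
    "KinConstants",
    "MicrotomeState",
    "AxisLimits",
    "SolutionEntry",
    "SolutionSet",
    "compute_constants",
    "forward_orientation",
    "block_orientation",
    "solve_sample_tilt",
    "solve_knife_tilt",
    "knife_angle_geometric",
    "verticality_residual",
    "sweep_solutions",
]

YHAT = np.array([0.0, 1.0, 0.0])
ZHAT = np.array([0.0, 0.0, 1.0])

#: |C3| below this, the verticality constraint no longer determines the tilt.
DEGENERACY_TOL = 1e-12


class DegenerateConfigurationError(ValueError):
    """The targeting geometry does not constrain the sample tilt
    (|C3| = |A*I + H| vanishes)."""


@dataclass(frozen=True)
class InitialAlignment:
    """Sample and knife tilt (degrees) at knife/block-face alignment."""

    theta_IT: float
    theta_IK: float

    def __post_init__(self):
        if not (math.isfinite(self.theta_IT) and math.isfinite(self.theta_IK)):
            raise ValueError("alignment angles must be finite")


@dataclass(frozen=True)
class MicrotomeState:
    """One machine pose: sample tilt, sample rotation, knife tilt (degrees)."""

    theta_T: float
    theta_R: float
    theta_K: float


@dataclass(frozen=True)
class AxisLimits:
    """Mechanical limits of the ultramicrotome axes."""

    sample_tilt_max: float = 20.0  # degrees
    knife_tilt_max: float = 45.0  # degrees; machine-specific, configurable
    rotation_range: float = 360.0  # degrees, full circle
    feed_length_um: float = 200.0  # uninterrupted cutting travel before a reset

    def __post_init__(self):
        if min(self.sample_tilt_max, self.knife_tilt_max, self.rotation_range, self.feed_length_um) <= 0:
            raise ValueError("axis limits must be positive")


@dataclass(frozen=True)
class KinConstants:
    """The nine setup constants A..I and the derived ratios C1..C5.

    Each of A..I is a product of sines/cosines of the four setup angles,
    so each lies in [-1, 1].  The derived constants are

        C1 = (-A*F + G) / (-A*I - H),   C2 = E / (-A*I - H),
        C3 = A*I + H,  C4 = E,  C5 = A*F - G.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float
    I: float

    @property
    def C3(self) -> float:
        return self.A * self.I + self.H

    @property
    def C4(self) -> float:
        return self.E

    @property
    def C5(self) -> float:
        return self.A * self.F - self.G

    @property
    def C1(self) -> float:
        return (-self.A * self.F + self.G) / (-self.C3)

    @property
    def C2(self) -> float:
        return self.E / (-self.C3)

    @property
    def degenerate(self) -> bool:
        return abs(self.C3) <= DEGENERACY_TOL


def compute_constants(align: InitialAlignment, offsets: TargetOffsets) -> KinConstants:
    """Evaluate the setup constants A..I for one targeting run."""
    it = math.radians(align.theta_IT)
    kt = math.radians(align.theta_IK + offsets.theta_to)
    tr = math.radians(offsets.theta_tr)
    return KinConstants(
        A=math.cos(kt),
        B=math.sin(tr) * math.sin(kt),
        C=math.sin(it) * math.sin(kt),
        D=math.cos(it) * math.sin(kt),
        E=math.cos(tr) * math.sin(kt),
        F=math.sin(it) * math.cos(tr),
        G=math.sin(tr) * math.cos(it),
        H=math.sin(it) * math.sin(tr),
        I=math.cos(it) * math.cos(tr),
    )


def forward_orientation(
    state: MicrotomeState, align: InitialAlignment, offsets: TargetOffsets
) -> Rotation3:
    """World orientation of the target-plane frame for a machine pose.

    F = Rx(theta_T) Ry(theta_R) Rx(-theta_IT) Rz(theta_IK)
        Rz(theta_to) Rx(theta_tr).
    The knife tilt does not enter F: it orients the knife, not the sample.
    """
    return (
        rotation_matrix("x", state.theta_T)
        @ rotation_matrix("y", state.theta_R)
        @ rotation_matrix("x", -align.theta_IT)
        @ rotation_matrix("z", align.theta_IK)
        @ rotation_matrix("z", offsets.theta_to)
        @ rotation_matrix("x", offsets.theta_tr)
    )


def block_orientation(state: MicrotomeState, align: InitialAlignment) -> Rotation3:
    """World orientation of the *block* frame for a machine pose: the
    forward product truncated before the target-offset rotations."""
    return (
        rotation_matrix("x", state.theta_T)
        @ rotation_matrix("y", state.theta_R)
        @ rotation_matrix("x", -align.theta_IT)
        @ rotation_matrix("z", align.theta_IK)
    )


def solve_sample_tilt(theta_R: float, k: KinConstants) -> float:
    """Closed-form sample tilt (degrees) that makes the target plane
    vertical at the given sample rotation:

        theta_T = arctan(C1 cos(theta_R) + C2 sin(theta_R))

    Principal value in (-90, 90); the theta_R + 180 deg entry carries the
    mirrored branch.
    """
    if k.degenerate:
        raise DegenerateConfigurationError(
            "sample tilt is unconstrained: |A*I + H| <= 1e-12"
        )
    r = math.radians(theta_R)
    return math.degrees(math.atan(k.C1 * math.cos(r) + k.C2 * math.sin(r)))


def solve_knife_tilt(theta_R: float, k: KinConstants) -> float:
    """Closed-form signed knife tilt (degrees) for the vertical-plane
    solution at the given sample rotation:

        theta_K = arctan( C3 (C4 cos + C5 sin)
                          / ( sqrt(C3^2 + (C4 sin - C5 cos)^2) |C3| ) )

    with all trig in theta_R.  Equals the signed horizontal-plane angle
    from World y to the transformed target normal F yhat (with theta_T
    substituted from :func:`solve_sample_tilt`).
    """
    if k.degenerate:
        raise DegenerateConfigurationError(
            "knife tilt is unconstrained: |A*I + H| <= 1e-12"
        )
    r = math.radians(theta_R)
    c, s = math.cos(r), math.sin(r)
    num = k.C3 * (k.C4 * c + k.C5 * s)
    den = math.sqrt(k.C3**2 + (k.C4 * s - k.C5 * c) ** 2) * abs(k.C3)
    return math.degrees(math.atan(num / den))


def knife_angle_geometric(
    theta_R: float, align: InitialAlignment, offsets: TargetOffsets, k: KinConstants
) -> float:
    """Knife angle from its geometric definition, as an independent check
    of the closed form: the signed angle in the horizontal plane from
    World y to F yhat, i.e. arctan(((yhat x F yhat) . zhat) / (yhat . F yhat)),
    with theta_T from the tilt solution."""
    theta_T = solve_sample_tilt(theta_R, k)
    F = forward_orientation(MicrotomeState(theta_T, theta_R, 0.0), align, offsets)
    fy = F @ YHAT
    num = float(np.dot(np.cross(YHAT, fy), ZHAT))
    den = float(np.dot(YHAT, fy))
    if den == 0.0:
        return math.copysign(90.0, num)
    # arctan of the ratio: principal branch (-90, 90).  The transformed
    # normal may point into the -y half-space (its sign is a convention);
    # the knife angle is defined modulo 180 within the reachable range.
    return math.degrees(math.atan(num / den))


def verticality_residual(
    state: MicrotomeState, align: InitialAlignment, offsets: TargetOffsets
) -> float:
    """|(F yhat) . zhat| — zero when the target plane is vertical."""
    F = forward_orientation(state, align, offsets)
    return abs(float(np.dot(F @ YHAT, ZHAT)))


@dataclass(frozen=True)
class SolutionEntry:
    theta_R: float
    theta_T: float
    theta_K: float
    feasible: bool
    residual: float


@dataclass(frozen=True)
class SolutionSet:
    """All vertical-plane solutions on a sample-rotation grid."""

    entries: tuple

    @property
    def theta_R(self) -> np.ndarray:
        return np.array([e.theta_R for e in self.entries])

    @property
    def theta_T(self) -> np.ndarray:
        return np.array([e.theta_T for e in self.entries])

    @property
    def theta_K(self) -> np.ndarray:
        return np.array([e.theta_K for e in self.entries])

    @property
    def feasible_mask(self) -> np.ndarray:
        return np.array([e.feasible for e in self.entries], dtype=bool)

    def feasible_entries(self):
        return [e for e in self.entries if e.feasible]

    def best_feasible(self, key=None) -> SolutionEntry:
        """Feasible entry minimising ``key`` (default: |theta_T| + |theta_K|,
        i.e. the least-extreme pose)."""
        feas = self.feasible_entries()
        if not feas:
            raise ValueError("no feasible solution within the axis limits")
        if key is None:
            key = lambda e: abs(e.theta_T) + abs(e.theta_K)
        return min(feas, key=key)


def sweep_solutions(
    align: InitialAlignment,
    offsets: TargetOffsets,
    limits: AxisLimits = AxisLimits(),
    step: float = 0.1,
) -> SolutionSet:
    """Evaluate the tilt/knife solutions on a theta_R grid over [-180, 180).

    Each entry is flagged feasible iff |theta_T| <= sample_tilt_max and
    |theta_K| <= knife_tilt_max; the verticality residual |(F yhat).zhat|
    is recorded per entry.  The default 0.1 degree grid matches the
    calibrated command resolution of the motorised axes.
    """
    if step <= 0:
        raise ValueError("grid step must be positive")
    k = compute_constants(align, offsets)
    if k.degenerate:
        raise DegenerateConfigurationError(
            "sample tilt is unconstrained: |A*I + H| <= 1e-12"
        )
    half = limits.rotation_range / 2.0
    grid = np.arange(-half, half, step)
    r = np.radians(grid)
    c, s = np.cos(r), np.sin(r)
    t_rad = np.arctan(k.C1 * c + k.C2 * s)
    theta_T = np.degrees(t_rad)
    num = k.C3 * (k.C4 * c + k.C5 * s)
    den = np.sqrt(k.C3**2 + (k.C4 * s - k.C5 * c) ** 2) * abs(k.C3)
    theta_K = np.degrees(np.arctan(num / den))
    # verticality residual |(F yhat).zhat|, in the setup-constant form
    res = np.abs(
        k.C3 * np.sin(t_rad) + (-k.C5 * c + k.C4 * s) * np.cos(t_rad)
    )
    feas = (np.abs(theta_T) <= limits.sample_tilt_max) & (np.abs(theta_K) <= limits.knife_tilt_max)
    entries = tuple(
        SolutionEntry(float(grid[i]), float(theta_T[i]), float(theta_K[i]), bool(feas[i]), float(res[i]))
        for i in range(grid.size)
    )
    return SolutionSet(entries)
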