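"""Elementary 3D geometry: rotations, planes, lines and frames.

All public angles are in degrees; all lengths are in micrometres (µm).
Rotations follow the active, right-handed convention and act on column
vectors from the left: a positive rotation about x carries y toward z,
about y carries z toward x, and about z carries x toward y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rotation3",
    "Plane",
    "Line3",
    "Frame3",
    "rotation_matrix",
    "fit_plane",
    "signed_distance",
    "angle_between_planes",
    "intersect_planes",
]

_ORTHO_TOL = 1e-10
_UNIT_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when an operation's input is geometrically degenerate
    (collinear point scatter, parallel planes, ...)."""


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite")
    return a


@dataclass(frozen=True)
class Rotation3:
    """Proper rotation: a 3x3 orthonormal matrix with determinant +1."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("Rotation3 requires a 3x3 matrix")
        if not np.allclose(m.T @ m, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("Rotation3 columns must be orthonormal")
        if not math.isclose(float(np.linalg.det(m)), 1.0, abs_tol=1e-9):
            raise ValueError("Rotation3 determinant must be +1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Rotation3":
        return cls(np.eye(3))

    def __matmul__(self, other):
        if isinstance(other, Rotation3):
            return Rotation3(self.matrix @ other.matrix)
        return self.matrix @ np.asarray(other, dtype=float)

    def apply(self, v) -> np.ndarray:
        """Rotate a 3-vector (or an (N, 3) stack of vectors)."""
        a = np.asarray(v, dtype=float)
        return a @ self.matrix.T

    @property
    def T(self) -> "Rotation3":
        return Rotation3(self.matrix.T)

    def inverse(self) -> "Rotation3":
        return self.T


@dataclass(frozen=True)
class Plane:
    """An infinite plane: unit normal plus a reference point (µm).

    ``normal`` and ``-normal`` describe the same geometric plane;
    operations that depend on the side state their sign convention.
    """

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self):
        n = _as_vec3(self.normal, "normal")
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "point", _as_vec3(self.point, "point"))

    def flipped(self) -> "Plane":
        return Plane(-self.normal, self.point)


@dataclass(frozen=True)
class Line3:
    """An infinite line: point (µm) plus unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        d = _as_vec3(self.direction, "direction")
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValueError("line direction must be nonzero")
        object.__setattr__(self, "direction", d / norm)
        object.__setattr__(self, "point", _as_vec3(self.point, "point"))


@dataclass(frozen=True)
class Frame3:
    """A right-handed coordinate frame: origin (µm) plus a Rotation3 whose
    columns are the frame's x, y, z axes expressed in World coordinates."""

    origin: np.ndarray
    basis: Rotation3

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        if not isinstance(self.basis, Rotation3):
            object.__setattr__(self, "basis", Rotation3(np.asarray(self.basis, dtype=float)))

    @property
    def x(self) -> np.ndarray:
        return self.basis.matrix[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.basis.matrix[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.basis.matrix[:, 2]

    def to_local(self, p) -> np.ndarray:
        """World -> frame coordinates."""
        return (np.asarray(p, dtype=float) - self.origin) @ self.basis.matrix

    def to_world(self, p) -> np.ndarray:
        """Frame -> World coordinates."""
        return np.asarray(p, dtype=float) @ self.basis.matrix.T + self.origin


def rotation_matrix(axis: str, angle_deg: float) -> Rotation3:
    """Active right-handed rotation about a World axis.

    Parameters
    ----------
    axis : {'x', 'y', 'z'}
    angle_deg : rotation angle in degrees (positive rotates y->z about x,
        z->x about y, x->y about z).
    """
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be one of 'x', 'y', 'z', got {axis!r}")
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    if axis == "x":
        m = [[1, 0, 0], [0, c, -s], [0, s, c]]
    elif axis == "y":
        m = [[c, 0, s], [0, 1, 0], [-s, 0, c]]
    else:
        m = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
    return Rotation3(np.array(m, dtype=float))


def fit_plane(points) -> Plane:
    """Total-least-squares plane through a scatter of 3D points.

    Minimises the sum of squared perpendicular distances; the reference
    point is the centroid and the normal is the singular vector of the
    centered scatter with the smallest singular value.  The normal sign is
    canonicalised so its z-component is >= 0 (ties: y >= 0, then x >= 0).

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a (near-)collinear scatter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centered scatter; singular values sorted descending.
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9:
        raise DegenerateGeometryError("points are collinear; plane is not unique")
    normal = vt[2]
    # canonical sign: z >= 0, tie-break y then x
    for comp in (2, 1, 0):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    return Plane(normal, centroid)


def signed_distance(p, plane: Plane) -> float:
    """Signed perpendicular distance (µm) from point to plane; the sign
    follows ``plane.normal``."""
    return float(np.dot(plane.normal, _as_vec3(p, "point") - plane.point))


def angle_between_planes(a: Plane, b: Plane) -> float:
    """Unsigned angle between two planes in degrees, in [0, 90].

    Computed as arccos(|n_a . n_b|), so it is invariant to the sign of
    either normal.
    """
    d = abs(float(np.dot(a.normal, b.normal)))
    return math.degrees(math.acos(min(d, 1.0)))


def intersect_planes(a: Plane, b: Plane) -> Line3:
    """Line of intersection of two non-parallel planes.

    The direction is the normalised cross product of the normals and the
    returned point is the minimum-norm point lying on both planes.

    Raises
    ------
    DegenerateGeometryError
        If the planes are parallel (|n_a x n_b| <= 1e-9).
    """
    cross = np.cross(a.normal, b.normal)
    norm = np.linalg.norm(cross)
    if norm <= 1e-9:
        raise DegenerateGeometryError("planes are parallel; no unique intersection")
    direction = cross / norm
    # Minimum-norm solution of the two plane equations n.p = d.
    A = np.vstack([a.normal, b.normal])
    d = np.array([np.dot(a.normal, a.point), np.dot(b.normal, b.point)])
    point, *_ = np.linalg.lstsq(A, d, rcond=None)
    return Line3(point, direction)
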