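"""Targeting-accuracy measures on registered before/after volumes.

After a targeting run the block is re-imaged and registered to the
pre-targeting scan; the reached block surface is then a plane fitted to
points on the after scan.  Three measures quantify how well the target
was hit:

* **angle error** — absolute angle between the target-plane normal and the
  after-surface normal, in [0, 90] degrees;
* **solution distance error** — signed difference between the NS distance
  actually cut (inferred from the after surface and the predicted
  first-touch point) and the recorded solution distance; positive means
  over-trimmed;
* **point-to-plane error** — absolute perpendicular distance from a marked
  point on the target plane to the after surface.

Fiducial registration error (mean Euclidean distance between matched
landmark pairs) summarises the registration uncertainty underlying all
three.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .annotation import BlockFace
from .cutting import oriented_target_normal
from .geometry import Plane, angle_between_planes, signed_distance

__all__ = [
    "AccuracyReport",
    "FiducialPairs",
    "FirstTouchMismatchWarning",
    "angle_error",
    "solution_distance_error",
    "point_to_plane_error",
    "registration_point_error",
]


class FirstTouchMismatchWarning(UserWarning):
    """The after surface implies a different first-touch corner than the
    solution predicted; the solution-distance error is then unreliable."""


@dataclass(frozen=True)
class AccuracyReport:
    angle_error_deg: float
    solution_distance_error_um: float
    point_to_plane_error_um: float

    def __post_init__(self):
        if not 0 <= self.angle_error_deg <= 90:
            raise ValueError("angle error must lie in [0, 90] degrees")


@dataclass(frozen=True)
class FiducialPairs:
    """Matched landmark pairs (µm), one per registered image."""

    before: np.ndarray
    after: np.ndarray

    def __post_init__(self):
        b = np.atleast_2d(np.asarray(self.before, dtype=float))
        a = np.atleast_2d(np.asarray(self.after, dtype=float))
        if b.shape != a.shape or b.shape[1] != 3 or b.shape[0] < 1:
            raise ValueError("before/after must be matching (N, 3) arrays with N >= 1")
        object.__setattr__(self, "before", b)
        object.__setattr__(self, "after", a)


def angle_error(target: Plane, after_surface: Plane) -> float:
    """Absolute angle between the target and after-surface normals
    (degrees, sign-invariant)."""
    return angle_between_planes(target, after_surface)


def solution_distance_error(
    first_touch: np.ndarray,
    after_surface: Plane,
    theta_K_sol: float,
    D_Sol: float,
    face: BlockFace | None = None,
) -> float:
    """Signed cutting-distance error (µm).

    The perpendicular distance from the predicted first-touch point to the
    after surface is converted to an NS distance with the solution knife
    angle, D_NS' = D_P' / cos(theta_K), and compared with the recorded
    solution distance: ``error = D_NS' - D_Sol``.  Positive: over-trimmed;
    negative: not trimmed enough.

    The measure assumes cutting really started at the predicted corner and
    at the solution knife angle; when ``face`` is supplied and the after
    surface implies a different farthest corner, a
    :class:`FirstTouchMismatchWarning` is emitted.
    """
    if abs(theta_K_sol) >= 90:
        raise ValueError("knife angle must satisfy |theta_K| < 90 degrees")
    d_p = abs(signed_distance(first_touch, after_surface))
    d_ns = d_p / math.cos(math.radians(theta_K_sol))
    if face is not None:
        n = oriented_target_normal(face, after_surface)
        oriented = Plane(n, after_surface.point)
        dists = {lab: signed_distance(v, oriented) for lab, v in face.vertices.items()}
        implied = max(dists, key=lambda lab: dists[lab])
        if not np.allclose(face.vertices[implied], np.asarray(first_touch, dtype=float)):
            warnings.warn(
                f"after surface implies first touch at {implied!r}, not at the "
                "predicted corner; solution-distance error may be erroneous",
                FirstTouchMismatchWarning,
            )
    return d_ns - D_Sol


def point_to_plane_error(target_point, after_surface: Plane) -> float:
    """Absolute perpendicular distance (µm) from a marked target-plane
    point to the after surface."""
    return abs(signed_distance(target_point, after_surface))


def registration_point_error(pairs: FiducialPairs):
    """Per-pair Euclidean distances and their mean (µm)."""
    d = np.linalg.norm(pairs.after - pairs.before, axis=1)
    return d, float(d.mean())
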