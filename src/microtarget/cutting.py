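"""Distance solution and cut prediction.

Once the orientation is solved the target plane is vertical, so reaching
it only requires feeding the knife north-south.  The perpendicular depth
``D_P`` is measured from the target plane to the farthest block-face
corner (the first-touch point); the feed is along NS while the knife is
tilted by ``theta_K``, so the commanded cutting distance is

    D_NS = D_P / cos(theta_K).

The module also predicts cutting progression: the exposed block face
after a partial feed, and oblique cross-sections of the micro-CT volume
along any plane ("cutting mode" previews).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .annotation import VERTEX_LABELS, BlockFace
from .geometry import Plane, signed_distance
from .kinematics import AxisLimits, MicrotomeState

__all__ = [
    "CutPlan",
    "Volume",
    "CrossSection",
    "TargetCropsFaceWarning",
    "perpendicular_depth",
    "oriented_target_normal",
    "cutting_distance",
    "exposed_face_plane",
    "resample_cross_section",
    "make_cut_plan",
]


class TargetCropsFaceWarning(UserWarning):
    """The target plane passes through the block face: at least one corner
    lies on the far side of the target."""


@dataclass(frozen=True)
class Volume:
    """A scalar 3D image with isotropic voxels.

    The intensity grid is indexed ``[z, y, x]`` (plane, row, column); the
    physical position of voxel ``(k, j, i)`` is
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size`` µm
    (voxel-center convention).
    """

    intensities: np.ndarray
    voxel_size_um: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 3D array")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def shape(self):
        return self.intensities.shape

    def physical_extent(self) -> np.ndarray:
        """(x, y, z) extent of the grid in µm."""
        return np.asarray(self.shape, dtype=float)[::-1] * self.voxel_size_um

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) µm -> fractional (z, y, x) voxel indices."""
        p = (np.asarray(points, dtype=float) - self.origin) / self.voxel_size_um - 0.5
        return p[..., ::-1]


@dataclass(frozen=True)
class CrossSection:
    """A 2D oblique section through a volume."""

    image: np.ndarray
    basis_u: np.ndarray  # in-plane axis 1, world coords
    basis_v: np.ndarray  # in-plane axis 2, world coords
    spacing_um: float
    plane: Plane


@dataclass(frozen=True)
class CutPlan:
    """A chosen solution plus its distance bookkeeping."""

    solution: MicrotomeState
    D_P: float  # perpendicular target depth, µm
    D_NS: float  # knife-compensated NS cutting distance, µm
    D_Sol: float  # recorded solution distance (== D_NS when freshly planned)
    first_touch: str  # vertex label
    resets_required: int
    crop_warning: bool = False

    def __post_init__(self):
        if abs(self.D_NS * math.cos(math.radians(self.solution.theta_K)) - self.D_P) > 1e-9:
            raise ValueError("inconsistent cut plan: D_NS * cos(theta_K) != D_P")


def oriented_target_normal(face: BlockFace, target: Plane) -> np.ndarray:
    """Target normal oriented so the block-face centroid is on its
    non-negative side (i.e. pointing out of the remaining block)."""
    n = target.normal
    if signed_distance(face.centroid, target) < 0:
        n = -n
    return n


def perpendicular_depth(face: BlockFace, target: Plane):
    """Perpendicular depth from the target plane to the farthest block-face
    corner, and which corner the knife touches first.

    The target normal is oriented so the face centroid has non-negative
    signed distance; ``D_P`` is the maximum signed distance over the four
    corners and the arg-max corner is the first-touch point (under the
    solution orientation the knife plane is parallel to the target, so the
    farthest corner is reached first).  Ties break in the order
    bottom-left, bottom-right, top-left, top-right.

    Emits :class:`TargetCropsFaceWarning` when some corner lies beyond the
    target (the target plane crops the face); raises if *all* corners do
    (nothing to cut).
    """
    n = oriented_target_normal(face, target)
    oriented = Plane(n, target.point)
    dists = {lab: signed_distance(face.vertices[lab], oriented) for lab in VERTEX_LABELS}
    first = max(VERTEX_LABELS, key=lambda lab: (dists[lab], -VERTEX_LABELS.index(lab)))
    d_p = dists[first]
    if d_p <= 0:
        raise ValueError("target plane lies beyond every block-face corner: nothing to cut")
    if min(dists.values()) < 0:
        warnings.warn(
            "target plane passes through the block face "
            f"(corner distances {dists})",
            TargetCropsFaceWarning,
        )
    return d_p, first


def cutting_distance(D_P: float, theta_K: float) -> float:
    """NS cutting distance compensated for the knife tilt:
    D_NS = D_P / cos(theta_K)."""
    if D_P < 0:
        raise ValueError("D_P must be non-negative")
    if abs(theta_K) >= 90:
        raise ValueError("knife angle must satisfy |theta_K| < 90 degrees")
    return D_P / math.cos(math.radians(theta_K))


def make_cut_plan(
    face: BlockFace,
    target: Plane,
    solution: MicrotomeState,
    limits: AxisLimits = AxisLimits(),
) -> CutPlan:
    """Bundle the distance solution for a chosen orientation solution."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", TargetCropsFaceWarning)
        d_p, first = perpendicular_depth(face, target)
        cropped = any(issubclass(w.category, TargetCropsFaceWarning) for w in caught)
    d_ns = cutting_distance(d_p, solution.theta_K)
    resets = max(0, math.ceil(d_ns / limits.feed_length_um) - 1)
    return CutPlan(
        solution=solution,
        D_P=d_p,
        D_NS=d_ns,
        D_Sol=d_ns,
        first_touch=first,
        resets_required=resets,
        crop_warning=cropped,
    )


def exposed_face_plane(
    target: Plane, D_P: float, d_cut: float, theta_K: float, block_side: np.ndarray | None = None
) -> Plane:
    """Plane of the exposed block surface after feeding ``d_cut`` µm.

    The exposed face stays parallel to the target at perpendicular offset
    ``D_P - d_cut * cos(theta_K)`` on the block side of the target; the
    offset reaches 0 at ``d_cut = D_NS``.  ``block_side`` supplies the
    out-of-block orientation of the target normal (default: ``target.normal``
    already points out of the remaining block).
    """
    if not 0 <= d_cut <= cutting_distance(D_P, theta_K) + 1e-9:
        raise ValueError("d_cut must lie in [0, D_NS]")
    n = target.normal if block_side is None else np.asarray(block_side, dtype=float)
    n = n / np.linalg.norm(n)
    offset = D_P - d_cut * math.cos(math.radians(theta_K))
    return Plane(n, target.point + offset * n)


def _in_plane_basis(normal: np.ndarray):
    """Deterministic in-plane axes: u = normalised projection of World x
    onto the plane (fallback World y when the plane is ~normal to x),
    v = normal x u."""
    n = normal / np.linalg.norm(normal)
    for seed in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        u = seed - np.dot(seed, n) * n
        nu = np.linalg.norm(u)
        if nu >= 1e-6:
            u = u / nu
            return u, np.cross(n, u)
    raise ValueError("could not build an in-plane basis")  # unreachable


def resample_cross_section(
    vol: Volume, plane: Plane, extent_um, spacing_um: float
) -> CrossSection:
    """Sample the volume on a regular grid in an arbitrary plane.

    The grid is centered at ``plane.point`` with half-extents
    ``extent_um = (half_u, half_v)`` µm along the deterministic in-plane
    axes; interpolation is trilinear with out-of-volume samples set to 0.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    u, v = _in_plane_basis(plane.normal)
    half_u, half_v = float(extent_um[0]), float(extent_um[1])
    us = np.arange(-half_u, half_u + spacing_um / 2, spacing_um)
    vs = np.arange(-half_v, half_v + spacing_um / 2, spacing_um)
    uu, vv = np.meshgrid(us, vs, indexing="xy")
    pts = plane.point + uu[..., None] * u + vv[..., None] * v
    idx = vol.world_to_index(pts)  # (..., 3) in (z, y, x)
    lo = idx.min(axis=(0, 1))
    hi = idx.max(axis=(0, 1))
    if np.any(hi < -0.5) or np.any(lo > np.asarray(vol.shape) - 0.5):
        raise ValueError("plane grid does not intersect the volume")
    coords = np.moveaxis(idx, -1, 0)
    img = map_coordinates(
        vol.intensities.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    return CrossSection(image=img, basis_u=u, basis_v=v, spacing_um=spacing_um, plane=plane)
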