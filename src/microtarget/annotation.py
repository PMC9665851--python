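"""Block-face annotations and target offset angles.

A targeting run starts from annotations made on a micro-CT volume of the
resin block: a cloud of points on the flat trimmed block surface, the
target plane, and the four labelled corners of the block face.  This
module turns those into the block coordinate frame and the two offset
angles relating the block face to the target plane:

* ``theta_to`` — target offset angle, the rotation about the block frame's
  z axis that carries the block x axis onto the intersection line of the
  target plane with the block x-y plane;
* ``theta_tr`` — target rotation angle, the subsequent rotation about the
  intermediate x axis that carries the block-face normal onto the target
  normal.

Applying Rz(theta_to) then Rx(theta_tr) to the block frame yields a frame
whose y axis is the target-plane normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    Frame3,
    Plane,
    Rotation3,
    fit_plane,
    rotation_matrix,
    signed_distance,
)

__all__ = [
    "VERTEX_LABELS",
    "BlockFace",
    "TargetOffsets",
    "AnnotationSet",
    "block_frame_from_face",
    "compute_target_offsets",
    "target_normal_from_offsets",
    "block_face_from_annotations",
    "validate_annotations",
    "validate_vertex_labels",
    "ValidationIssue",
]

#: Canonical corner labels, in tie-break precedence order.
VERTEX_LABELS = ("bottom_left", "bottom_right", "top_left", "top_right")

DEFAULT_VERTEX_TOL_UM = 2.0  # ~2 voxels at 1 µm isotropic voxel size


@dataclass(frozen=True)
class BlockFace:
    """The trimmed block face: four labelled corner vertices (µm) plus the
    plane fitted to the block surface."""

    vertices: dict
    plane: Plane

    def __post_init__(self):
        verts = {k: np.asarray(v, dtype=float) for k, v in self.vertices.items()}
        missing = set(VERTEX_LABELS) - set(verts)
        if missing:
            raise ValueError(f"missing block-face vertices: {sorted(missing)}")
        extra = set(verts) - set(VERTEX_LABELS)
        if extra:
            raise ValueError(f"unknown block-face vertex labels: {sorted(extra)}")
        if np.allclose(verts["bottom_left"], verts["bottom_right"]):
            raise ValueError("bottom_left and bottom_right coincide")
        object.__setattr__(self, "vertices", verts)

    @property
    def centroid(self) -> np.ndarray:
        return np.mean([self.vertices[k] for k in VERTEX_LABELS], axis=0)

    def vertex_array(self) -> np.ndarray:
        """Vertices stacked in canonical label order, shape (4, 3)."""
        return np.stack([self.vertices[k] for k in VERTEX_LABELS])


@dataclass(frozen=True)
class TargetOffsets:
    """Offset angles (degrees) relating block face to target plane."""

    theta_to: float
    theta_tr: float

    def __post_init__(self):
        if not (-180.0 < self.theta_to <= 180.0):
            raise ValueError("theta_to must lie in (-180, 180]")
        if not (-90.0 <= self.theta_tr <= 90.0):
            raise ValueError("theta_tr must lie in [-90, 90]")


@dataclass(frozen=True)
class AnnotationSet:
    """Everything annotated on one micro-CT volume for a targeting run."""

    block_points: np.ndarray
    target_plane: Plane
    block_face: BlockFace
    voxel_size_um: float
    image_shape: tuple
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = np.asarray(self.block_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("block_points must be (N, 3)")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        object.__setattr__(self, "block_points", pts)
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))


def block_frame_from_face(face: BlockFace) -> Frame3:
    """Construct the block coordinate frame from the four labelled corners.

    The origin is the centroid of the four vertices.  x runs along the
    bottom edge (bottom-left to bottom-right); z is the component of the
    bottom-to-top midpoint direction orthogonal to x; y = z x x completes
    a right-handed frame and is the face normal.  With corners labelled as
    seen from outside the block (left/right as the viewer's left/right),
    y points out of the block, toward the knife.
    """
    v = face.vertices
    x = v["bottom_right"] - v["bottom_left"]
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise DegenerateGeometryError("bottom edge has zero length")
    x = x / nx
    top_mid = 0.5 * (v["top_left"] + v["top_right"])
    bottom_mid = 0.5 * (v["bottom_left"] + v["bottom_right"])
    up = top_mid - bottom_mid
    z = up - np.dot(up, x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise DegenerateGeometryError("block face is degenerate: top and bottom edges collinear")
    z = z / nz
    y = np.cross(z, x)
    basis = Rotation3(np.column_stack([x, y, z]))
    return Frame3(face.centroid, basis)


def block_face_from_annotations(ann: AnnotationSet, project: bool = True) -> BlockFace:
    """Build the BlockFace used for targeting from an annotation set.

    The block plane is fitted (total least squares) to the annotated
    surface points and, when ``project`` is true, the four corner vertices
    are projected perpendicularly onto that fitted plane.  Projection makes
    the face exactly planar, so the block frame inherits the fitted plane's
    orientation rather than the raw (noisy) corner clicks.
    """
    plane = fit_plane(ann.block_points)
    verts = {}
    for label, p in ann.block_face.vertices.items():
        if project:
            p = p - signed_distance(p, plane) * plane.normal
        verts[label] = p
    return BlockFace(verts, plane)


def _canonical_target_direction(block: Frame3, target: Plane) -> np.ndarray:
    """Target normal in block coordinates, sign-canonicalised.

    A plane has two normals; choose the representative with a non-negative
    block-y component (ties: positive block-z, then block-x) so that
    (theta_to, theta_tr) are deterministic with |theta_to| <= 90.
    """
    m = target.normal @ block.basis.matrix  # world -> block coordinates
    for comp in (1, 2, 0):
        if abs(m[comp]) > 1e-12:
            if m[comp] < 0:
                m = -m
            break
    return m


def compute_target_offsets(block: Frame3, target: Plane) -> TargetOffsets:
    """Offset angles (theta_to, theta_tr) from block frame to target plane.

    Writing the (canonicalised) target normal in block coordinates as m,
    the construction m = Rz(theta_to) Rx(theta_tr) yhat gives

        m = (-sin(theta_to) cos(theta_tr),
              cos(theta_to) cos(theta_tr),
              sin(theta_tr)),

    hence theta_tr = arcsin(m_z) and theta_to = atan2(-m_x, m_y).

    Degenerate case: if the target plane is parallel to the block x-y
    plane (normal along block z) the intersection line is undefined; by
    convention theta_to = 0 and theta_tr = +/-90.
    """
    m = _canonical_target_direction(block, target)
    mz = float(np.clip(m[2], -1.0, 1.0))
    theta_tr = math.degrees(math.asin(mz))
    if math.hypot(m[0], m[1]) < 1e-12:
        theta_to = 0.0  # target parallel to block x-y plane: any theta_to works
    else:
        theta_to = math.degrees(math.atan2(-m[0], m[1]))
    return TargetOffsets(theta_to=theta_to, theta_tr=theta_tr)


def target_normal_from_offsets(block: Frame3, offsets: TargetOffsets) -> np.ndarray:
    """World-coordinate target normal for given offsets: the y axis of the
    block frame composed with Rz(theta_to) Rx(theta_tr)."""
    r = rotation_matrix("z", offsets.theta_to) @ rotation_matrix("x", offsets.theta_tr)
    return block.basis.matrix @ (r.matrix @ np.array([0.0, 1.0, 0.0]))


def validate_vertex_labels(labels):
    """Check a raw sequence of corner labels (as read from a file, before
    a :class:`BlockFace` is built) for duplicates and missing entries.
    Returns a list of :class:`ValidationIssue`."""
    issues = []
    seen = list(labels)
    for label in VERTEX_LABELS:
        n = seen.count(label)
        if n == 0:
            issues.append(ValidationIssue("vertices", f"missing vertex label {label!r}"))
        elif n > 1:
            issues.append(ValidationIssue("vertices", f"duplicate vertex label {label!r}"))
    for label in seen:
        if label not in VERTEX_LABELS:
            issues.append(ValidationIssue("vertices", f"unknown vertex label {label!r}"))
    return issues


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    message: str
    severity: str = "error"  # or "warning"


def validate_annotations(ann: AnnotationSet, tol_um: float = DEFAULT_VERTEX_TOL_UM):
    """Check an annotation set for internal consistency.

    Returns a list of :class:`ValidationIssue`; an empty list means the
    annotations are consistent.  Content problems are reported, never
    raised.
    """
    issues = []
    try:
        plane = fit_plane(ann.block_points)
    except DegenerateGeometryError as exc:
        issues.append(ValidationIssue("block_points", str(exc)))
        plane = ann.block_face.plane
    for label in VERTEX_LABELS:
        p = ann.block_face.vertices.get(label)
        if p is None:
            issues.append(ValidationIssue("vertices", f"missing vertex {label!r}"))
            continue
        d = abs(signed_distance(p, plane))
        if d > tol_um:
            issues.append(
                ValidationIssue(
                    "vertex_off_plane",
                    f"vertex {label!r} lies {d:.2f} µm from the fitted block plane "
                    f"(tolerance {tol_um:g} µm)",
                )
            )
        extent = np.asarray(ann.image_shape, dtype=float)[::-1] * ann.voxel_size_um
        if np.any(np.asarray(p) < 0.0) or np.any(np.asarray(p) > extent):
            issues.append(
                ValidationIssue("vertex_out_of_bounds", f"vertex {label!r} outside image bounds")
            )
    cross = np.cross(plane.normal, ann.target_plane.normal)
    if np.linalg.norm(cross) <= 1e-9:
        issues.append(
            ValidationIssue(
                "parallel_planes",
                "target plane is parallel to the block plane",
                severity="warning",
            )
        )
    return issues
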