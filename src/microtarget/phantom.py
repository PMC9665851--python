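"""Synthetic micro-CT phantoms with exact ground truth.

A phantom emulates a lab micro-CT scan of a resin-embedded sample: a
homogeneous mid-intensity block (a trapezoidal prism with a flat trimmed
face) containing bright ellipsoidal inclusions, on a dark background,
voxelised at ~1 µm isotropic resolution with optional additive Gaussian
noise.  The block-face corners, block plane and target plane are derived
analytically from the generating parameters — never from the rasterised
image — so every downstream computation can be checked against exact
ground truth.

The module also simulates a complete targeting run on a phantom: annotate
the block surface (with optional jitter emulating manual point placement),
solve the orientation and distance, and predict the plane physically
reached by the knife, so that the accuracy measures can be evaluated
against a known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import (
    AnnotationSet,
    BlockFace,
    TargetOffsets,
    block_face_from_annotations,
    block_frame_from_face,
    compute_target_offsets,
    target_normal_from_offsets,
)
from .cutting import CutPlan, Volume, make_cut_plan
from .geometry import Plane, Rotation3, rotation_matrix, signed_distance
from .kinematics import (
    AxisLimits,
    InitialAlignment,
    MicrotomeState,
    block_orientation,
    sweep_solutions,
)

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "GroundTruth",
    "SimulatedCut",
    "generate_phantom",
    "ground_truth_annotations",
    "simulate_targeting_run",
]


@dataclass(frozen=True)
class Ellipsoid:
    """An ellipsoidal inclusion, in block-local coordinates (µm).

    The block-local frame has x along the bottom edge of the face, y the
    outward face normal (the block occupies y < 0) and z from the bottom
    edge toward the top edge.
    """

    center: tuple
    radii: tuple
    intensity: float


@dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters for one phantom volume.

    Face geometry is a trapezium: ``bottom_width`` and ``top_width`` may
    differ (equal widths give a rectangle).  The block prism extends
    ``depth`` µm behind the face.  ``orientation``/``translation`` place
    the block-local frame in the image (translation = world position of
    the bottom-edge midpoint).  The target plane is constructed from the
    block frame at the given offset angles, ``target_depth`` µm behind the
    face centroid.
    """

    bottom_width: float = 120.0
    top_width: float = 90.0
    height: float = 100.0
    depth: float = 80.0
    orientation: Rotation3 = field(
        default_factory=lambda: (
            rotation_matrix("z", 8.0) @ rotation_matrix("y", -6.0) @ rotation_matrix("x", 4.0)
        )
    )
    translation: tuple = (72.0, 90.0, 20.0)
    inclusions: tuple = (
        Ellipsoid(center=(0.0, -35.0, 50.0), radii=(22.0, 18.0, 25.0), intensity=255.0),
        Ellipsoid(center=(-25.0, -25.0, 30.0), radii=(8.0, 8.0, 8.0), intensity=200.0),
    )
    resin_intensity: float = 128.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    voxel_size_um: float = 1.0
    image_shape: tuple = (144, 144, 144)  # (z, y, x)
    theta_to: float = -3.3
    theta_tr: float = 5.4
    target_depth_um: float = 60.0
    alignment: InitialAlignment = field(default_factory=lambda: InitialAlignment(10.0, 10.0))
    seed: int = 0

    def __post_init__(self):
        if min(self.bottom_width, self.top_width, self.height, self.depth) <= 0:
            raise ValueError("face widths, height and depth must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")
        if self.target_depth_um <= 0:
            raise ValueError("target depth must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one phantom: face, target and setup angles."""

    block_face: BlockFace
    target_plane: Plane
    offsets: TargetOffsets
    alignment: InitialAlignment
    voxel_size_um: float
    image_shape: tuple


def _local_corners(spec: PhantomSpec) -> dict:
    hb, ht = spec.bottom_width / 2.0, spec.top_width / 2.0
    return {
        "bottom_left": np.array([-hb, 0.0, 0.0]),
        "bottom_right": np.array([hb, 0.0, 0.0]),
        "top_left": np.array([-ht, 0.0, spec.height]),
        "top_right": np.array([ht, 0.0, spec.height]),
    }


def _ground_truth(spec: PhantomSpec) -> GroundTruth:
    R = spec.orientation.matrix
    t = np.asarray(spec.translation, dtype=float)
    verts = {lab: R @ p + t for lab, p in _local_corners(spec).items()}
    face_normal = R @ np.array([0.0, 1.0, 0.0])
    centroid = np.mean(list(verts.values()), axis=0)
    face = BlockFace(verts, Plane(face_normal, centroid))
    frame = block_frame_from_face(face)
    offsets = TargetOffsets(spec.theta_to, spec.theta_tr)
    n_target = target_normal_from_offsets(frame, offsets)
    target = Plane(n_target, centroid - spec.target_depth_um * n_target)
    return GroundTruth(
        block_face=face,
        target_plane=target,
        offsets=offsets,
        alignment=spec.alignment,
        voxel_size_um=spec.voxel_size_um,
        image_shape=tuple(spec.image_shape),
    )


def generate_phantom(spec: PhantomSpec):
    """Voxelise a phantom and return ``(Volume, GroundTruth)``.

    Voxel membership is decided by the voxel-center point (no
    antialiasing); noise is additive Gaussian, clipped to [0, 255], and
    reproducible from ``spec.seed``.

    Raises if any block-face corner falls outside the image bounds.
    """
    gt = _ground_truth(spec)
    shape = tuple(int(s) for s in spec.image_shape)
    extent = np.asarray(shape, dtype=float)[::-1] * spec.voxel_size_um
    for lab, v in gt.block_face.vertices.items():
        if np.any(v < 0) or np.any(v > extent):
            raise ValueError(f"block corner {lab!r} at {v} exceeds the image bounds {extent}")

    # voxel-center world coordinates, axes ordered (x, y, z)
    zc, yc, xc = [
        (np.arange(n, dtype=np.float64) + 0.5) * spec.voxel_size_um for n in shape
    ]
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")  # note: transposed later
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    R = spec.orientation.matrix
    t = np.asarray(spec.translation, dtype=float)
    q = (pts - t) @ R  # world -> block-local

    half_w = 0.5 * (
        spec.bottom_width + (spec.top_width - spec.bottom_width) * np.clip(q[:, 2] / spec.height, 0, 1)
    )
    in_block = (
        (q[:, 1] >= -spec.depth)
        & (q[:, 1] <= 0.0)
        & (q[:, 2] >= 0.0)
        & (q[:, 2] <= spec.height)
        & (np.abs(q[:, 0]) <= half_w)
    )
    img = np.full(q.shape[0], spec.background_intensity, dtype=np.float32)
    img[in_block] = spec.resin_intensity
    for inc in spec.inclusions:
        c = np.asarray(inc.center, dtype=float)
        r = np.asarray(inc.radii, dtype=float)
        inside = np.sum(((q - c) / r) ** 2, axis=1) <= 1.0
        img[inside] = inc.intensity

    vol = img.reshape(len(xc), len(yc), len(zc)).T  # -> (z, y, x)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)
        vol = np.clip(vol, 0.0, 255.0)
    return Volume(np.ascontiguousarray(vol), spec.voxel_size_um), gt


def ground_truth_annotations(
    gt: GroundTruth,
    n_surface_points: int = 200,
    jitter_sd_um: float = 0.0,
    seed: int = 0,
) -> AnnotationSet:
    """Emulate manual annotation of a phantom.

    Samples ``n_surface_points`` uniformly over the block face (bilinear
    in the labelled quad) and perturbs them with isotropic Gaussian jitter
    of the given standard deviation, emulating the manual placement of
    surface points.  The corner vertices and target plane are copied
    exactly.
    """
    if n_surface_points < 3:
        raise ValueError("need at least 3 surface points")
    rng = np.random.default_rng(seed)
    v = gt.block_face.vertices
    u = rng.uniform(size=n_surface_points)
    s = rng.uniform(size=n_surface_points)
    pts = (
        (1 - s)[:, None] * ((1 - u)[:, None] * v["bottom_left"] + u[:, None] * v["bottom_right"])
        + s[:, None] * ((1 - u)[:, None] * v["top_left"] + u[:, None] * v["top_right"])
    )
    if jitter_sd_um > 0:
        pts = pts + rng.normal(0.0, jitter_sd_um, size=pts.shape)
    return AnnotationSet(
        block_points=pts,
        target_plane=gt.target_plane,
        block_face=BlockFace(dict(v), gt.block_face.plane),
        voxel_size_um=gt.voxel_size_um,
        image_shape=gt.image_shape,
    )


@dataclass(frozen=True)
class SimulatedCut:
    """Outcome of a simulated targeting run on a phantom."""

    offsets: TargetOffsets
    solution: MicrotomeState
    plan: CutPlan
    reached_plane: Plane
    predicted_first_touch_point: np.ndarray


def simulate_targeting_run(
    gt: GroundTruth,
    ann: AnnotationSet,
    limits: AxisLimits = AxisLimits(),
    step: float = 0.1,
    solution_key=None,
) -> SimulatedCut:
    """Run the full targeting pipeline on annotations and predict the
    physically reached plane.

    The pipeline side uses only the annotations: fit the block plane,
    project the corners, build the block frame, measure the target
    offsets, sweep the solutions and pick a feasible one (default: the
    least-extreme pose), then compute the cutting distances.

    The physical side uses the ground truth: at alignment the knife frame
    coincides with the *true* block frame, so the machine pose carries the
    true block to orientation ``W_B``; the knife plane is vertical with
    horizontal normal at the solution knife angle.  Mapping that plane
    back into image coordinates and feeding the solution NS distance from
    the true first-touched corner gives the reached plane.  Annotation
    error therefore propagates into the reached plane exactly as it would
    on the instrument.
    """
    face_est = block_face_from_annotations(ann)
    frame_est = block_frame_from_face(face_est)
    offsets_est = compute_target_offsets(frame_est, ann.target_plane)
    solutions = sweep_solutions(gt.alignment, offsets_est, limits, step)
    entry = solutions.best_feasible(solution_key)
    state = MicrotomeState(entry.theta_T, entry.theta_R, entry.theta_K)
    plan = make_cut_plan(face_est, ann.target_plane, state, limits)

    # physical side: knife plane orientation in image coordinates
    B_true = block_frame_from_face(gt.block_face).basis
    W_B = block_orientation(state, gt.alignment)
    knife_normal_world = rotation_matrix("z", state.theta_K) @ np.array([0.0, 1.0, 0.0])
    n_img = B_true.matrix @ (W_B.matrix.T @ knife_normal_world)
    if float(np.dot(n_img, gt.block_face.plane.normal)) < 0:
        n_img = -n_img  # orient out of the block
    # the knife first touches the corner farthest along the cut normal
    dists = {lab: float(np.dot(v, n_img)) for lab, v in gt.block_face.vertices.items()}
    touch_lab = max(dists, key=lambda lab: dists[lab])
    touch = gt.block_face.vertices[touch_lab]
    advance = plan.D_NS * math.cos(math.radians(state.theta_K))
    reached = Plane(n_img, touch - advance * n_img)
    return SimulatedCut(
        offsets=offsets_est,
        solution=state,
        plan=plan,
        reached_plane=reached,
        predicted_first_touch_point=face_est.vertices[plan.first_touch],
    )
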