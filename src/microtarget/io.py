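"""Record and volume I/O.

Annotations, solutions, cut plans and accuracy reports are stored as
versioned JSON records; volumes as multi-page grayscale TIFF stacks.
Unknown extra fields in records are preserved on read (best-effort
compatibility with externally produced files) but ignored for
computation.  All coordinates in records are physical µm; voxel indices
are 0-based with the voxel-center convention
``physical = origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .accuracy import AccuracyReport, FiducialPairs
from .annotation import AnnotationSet, BlockFace, TargetOffsets, VERTEX_LABELS
from .cutting import CutPlan, Volume
from .geometry import Plane
from .kinematics import AxisLimits, InitialAlignment, MicrotomeState

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_annotations",
    "write_annotations",
    "read_volume",
    "write_volume",
    "to_8bit",
    "flip_volume",
    "write_solution",
    "read_solution",
    "write_accuracy_report",
    "read_fiducial_pairs",
    "read_calibration_table",
    "file_sha256",
]

log = logging.getLogger("microtarget")

ANNOTATION_SCHEMA = "microtarget-annotations/1"
SOLUTION_SCHEMA = "microtarget-solution/1"
MEASURES_SCHEMA = "microtarget-measures/1"

_ANNOTATION_FIELDS = ("voxel_size_um", "image_shape", "block_points", "target_plane", "vertices")


class SchemaError(ValueError):
    """A record file is missing a required field or is malformed."""


@dataclass(frozen=True)
class RunConfig:
    """Knobs shared across the workflow stages."""

    limits: AxisLimits = field(default_factory=AxisLimits)
    rotation_step_deg: float = 0.1
    vertex_tol_um: float = 2.0
    cut_preview_step_um: float = 5.0
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        if self.rotation_step_deg <= 0 or self.vertex_tol_um <= 0 or self.cut_preview_step_um <= 0:
            raise ValueError("steps and tolerances must be positive")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- annotations


def write_annotations(ann: AnnotationSet, path) -> None:
    rec = {
        "schema": ANNOTATION_SCHEMA,
        "software_version": __version__,
        "voxel_size_um": ann.voxel_size_um,
        "image_shape": list(ann.image_shape),
        "block_points": np.asarray(ann.block_points).tolist(),
        "target_plane": {
            "normal": ann.target_plane.normal.tolist(),
            "point": ann.target_plane.point.tolist(),
        },
        "block_plane": {
            "normal": ann.block_face.plane.normal.tolist(),
            "point": ann.block_face.plane.point.tolist(),
        },
        "vertices": {lab: ann.block_face.vertices[lab].tolist() for lab in VERTEX_LABELS},
    }
    rec.update(ann.extra)
    Path(path).write_text(json.dumps(rec, indent=1))


def read_annotations(path) -> AnnotationSet:
    try:
        rec = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed annotation file {path}: {exc}") from exc
    for key in _ANNOTATION_FIELDS:
        if key not in rec:
            raise SchemaError(f"annotation file {path} is missing required field {key!r}")
    tp = rec["target_plane"]
    target = Plane(np.asarray(tp["normal"], float), np.asarray(tp["point"], float))
    verts = {lab: np.asarray(v, float) for lab, v in rec["vertices"].items()}
    if "block_plane" in rec:
        bp = rec["block_plane"]
        plane = Plane(np.asarray(bp["normal"], float), np.asarray(bp["point"], float))
    else:
        from .geometry import fit_plane

        plane = fit_plane(np.asarray(rec["block_points"], float))
    known = set(_ANNOTATION_FIELDS) | {"schema", "software_version", "block_plane"}
    extra = {k: v for k, v in rec.items() if k not in known}
    return AnnotationSet(
        block_points=np.asarray(rec["block_points"], float),
        target_plane=target,
        block_face=BlockFace(verts, plane),
        voxel_size_um=float(rec["voxel_size_um"]),
        image_shape=tuple(rec["image_shape"]),
        extra=extra,
    )


# -------------------------------------------------------------------- volumes


def write_volume(vol: Volume, path) -> None:
    """Write a volume as a multi-page grayscale TIFF with the voxel size
    recorded in ImageJ-style metadata.  Byte-stable for integer grids."""
    arr = vol.intensities
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    tifffile.imwrite(
        path,
        arr,
        imagej=arr.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
        resolution=(1.0 / vol.voxel_size_um, 1.0 / vol.voxel_size_um),
        metadata={"spacing": vol.voxel_size_um, "unit": "um", "axes": "ZYX"},
    )


def read_volume(path, voxel_size_um: float | None = None) -> Volume:
    """Read a multi-page grayscale TIFF.  The voxel size is taken from
    ImageJ metadata when present, else must be supplied."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if voxel_size_um is None:
            meta = tif.imagej_metadata or {}
            voxel_size_um = meta.get("spacing")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout with shape {arr.shape}: expected a grayscale "
            "stack (RGB/multi-channel images are not supported)"
        )
    if voxel_size_um is None:
        raise ValueError("voxel size not found in TIFF metadata; pass voxel_size_um")
    return Volume(arr, float(voxel_size_um))


def flip_volume(vol: Volume, flip_y: bool = False, flip_z: bool = False) -> Volume:
    """Mirror the grid along y and/or z (the standard preprocessing fix
    when the scan appears as a mirror image of the physical block).  The
    applied flips are logged for provenance."""
    arr = vol.intensities
    if flip_y:
        arr = arr[:, ::-1, :]
        log.info("flip_volume: mirrored along y")
    if flip_z:
        arr = arr[::-1, :, :]
        log.info("flip_volume: mirrored along z")
    return Volume(np.ascontiguousarray(arr), vol.voxel_size_um, vol.origin)


def to_8bit(vol: Volume) -> Volume:
    """Linearly rescale any grid to 8-bit: min -> 0, max -> 255.

    The applied mapping is logged so conversions are reproducible.
    """
    arr = vol.intensities.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        out = np.zeros_like(arr, dtype=np.uint8)
        log.info("to_8bit: constant volume (value %g) mapped to 0", lo)
    else:
        out = np.clip(np.round((arr - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)
        log.info("to_8bit: linear rescale [%g, %g] -> [0, 255]", lo, hi)
    return Volume(out, vol.voxel_size_um, vol.origin)


# -------------------------------------------------------------------- records


def write_solution(
    path,
    state: MicrotomeState,
    align: InitialAlignment,
    offsets: TargetOffsets,
    plan: CutPlan | None = None,
    feasible: bool = True,
) -> None:
    rec = {
        "schema": SOLUTION_SCHEMA,
        "software_version": __version__,
        "theta_R": state.theta_R,
        "theta_T": state.theta_T,
        "theta_K": state.theta_K,
        "feasible": bool(feasible),
        "parameters": {
            "theta_IT": align.theta_IT,
            "theta_IK": align.theta_IK,
            "theta_to": offsets.theta_to,
            "theta_tr": offsets.theta_tr,
        },
    }
    if plan is not None:
        rec.update(
            {
                "D_P_um": plan.D_P,
                "D_NS_um": plan.D_NS,
                "first_touch": plan.first_touch,
                "resets_required": plan.resets_required,
            }
        )
    Path(path).write_text(json.dumps(rec, indent=1))


def read_solution(path) -> dict:
    try:
        rec = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed solution file {path}: {exc}") from exc
    for key in ("theta_R", "theta_T", "theta_K", "parameters"):
        if key not in rec:
            raise SchemaError(f"solution file {path} is missing required field {key!r}")
    return rec


def write_accuracy_report(report: AccuracyReport, path, extra: dict | None = None) -> None:
    rec = {
        "schema": MEASURES_SCHEMA,
        "software_version": __version__,
        **dataclasses.asdict(report),
    }
    if extra:
        rec.update(extra)
    Path(path).write_text(json.dumps(rec, indent=1))


# --------------------------------------------------------------------- tables


def read_fiducial_pairs(path, voxel_size_um: float = 1.0) -> FiducialPairs:
    """Read matched landmark pairs from a comma-separated table with one
    pair per row: ``x1,y1,z1,x2,y2,z2``.  Values are multiplied by
    ``voxel_size_um`` (use 1.0 when the table is already in µm)."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
    if arr.shape[1] != 6:
        raise SchemaError("fiducial table must have 6 columns: x1,y1,z1,x2,y2,z2")
    arr = arr * voxel_size_um
    return FiducialPairs(arr[:, :3], arr[:, 3:])


def read_calibration_table(path) -> np.ndarray:
    """Read a two-column comma-separated calibration table
    (microsteps, dial degrees)."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
    if arr.shape[1] != 2:
        raise SchemaError("calibration table must have 2 columns: microsteps, degrees")
    return arr
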