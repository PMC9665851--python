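# Methods

## Model and coordinate conventions

The instrument is modelled as three rotational degrees of freedom acting
on a rigid block: sample tilt θ_T about World x, sample rotation θ_R
about the tilted holder's axis, and knife tilt θ_K about World z.  World
axes: x = east–west knife translation, y = north–south feed, z =
vertical.  All public angles are degrees; all lengths are µm.  Rotations
are active, right-handed, applied to column vectors on the left
(positive x-rotation carries y toward z, etc.).  This convention is not
printed anywhere as a matrix identity; it is pinned down behaviourally
by the verticality property (every solved pose leaves the transformed
target normal horizontal) and by closed-form limiting cases (a pure
target offset o gives θ_K(0) = o; a pure target rotation t gives
θ_T(0) = −t), both under test.

The relation between block and holder is unknown a priori (the holder
does not grip the block reproducibly), so it is inferred from a manual
alignment step: when the knife is aligned to the block face, the knife
and block frames coincide, sample rotation is defined as zero, and the
current tilts (θ_IT, θ_IK) become constants of the run.  The target
plane is related to the block frame by two measured offsets: θ_to about
block z, then θ_tr about the intermediate x; applying Rz(θ_to)·Rx(θ_tr)
to the block frame yields a frame whose y axis is the target normal.

The forward kinematics product, the setup constants A–I, and the
closed-form tilt/knife solutions are as stated in the README.  Three
independent guards protect the closed forms:

1. a bracketing root finder on (F·ŷ)·ẑ = 0 in θ_T reproduces the tilt
   solution to 1e-8°;
2. the geometric knife angle arctan(((ŷ×Fŷ)·ẑ)/(ŷ·Fŷ)), evaluated from
   the rotation-matrix product, reproduces the knife solution to 1e-8°;
3. a SymPy re-derivation from the forward product confirms both closed
   forms term-by-term (`microtarget.derivation`).

The knife solution's principal branch is (−90°, 90°); the θ_R + 180°
grid entry carries the mirrored branch (θ_T, θ_K both change sign), so
no multi-branch handling is needed inside the closed forms.  The
geometric knife angle is defined as an arctan of a ratio rather than a
full atan2: the transformed normal's sign is a convention, and an atan2
branch beyond ±90° would describe a knife orientation the holder cannot
reach anyway.

## Offset-angle representatives

A plane has two normals, so (θ_to, θ_tr) has two equivalent
representatives, (θ_to, θ_tr) and (θ_to ± 180°, −θ_tr).
`compute_target_offsets` canonicalises the normal so its block-y
component is ≥ 0 (ties: block-z, then block-x positive), which selects
the representative with θ_to ∈ [−90°, 90°].  Round-trip recovery is
therefore exact on that domain and is tested there; supplying either
normal sign yields the identical result.  When the target is parallel to
the block x–y plane the intersection line defining θ_to is undefined and
θ_to = 0 is returned by convention (with θ_tr = ±90°); when the target
is parallel to the block face both offsets are 0.

## Degeneracy and numerical thresholds

- |C3| = |AI + H| ≤ 1e-12: the verticality constraint no longer
  determines the tilt; the solvers raise rather than guess.
- Plane fitting is total least squares via SVD of the centered scatter;
  a second singular value below 1e-9 signals a collinear scatter.
  Fitted normals are canonicalised to z ≥ 0 (ties y, then x); operations
  needing an out-of-block orientation re-orient explicitly.
- Parallel planes are detected at |n_a × n_b| ≤ 1e-9.
- First-touch ties break in the fixed order bottom-left, bottom-right,
  top-left, top-right.
- Microstep rounding is half-away-from-zero, symmetric about 0°.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| sample_tilt_max | 20° | arc-piece tilt range of both supported instruments |
| knife_tilt_max | 45° | knife-holder range; not published, configurable |
| feed_length_um | 200 µm | uninterrupted feed before a manual reset; resets_required = ceil(D_NS/feed) − 1 |
| rotation grid step | 0.1° | the calibrated command resolution of the motorised axes |
| vertex tolerance | 2 µm | ≈ 2 voxels at 1 µm isotropic voxel size |
| cut-preview step | 5 µm | progression-stack spacing, inclusive endpoints |

The block coordinate frame is built from the four labelled corners:
origin at their centroid, x along the bottom edge (bottom-left →
bottom-right), z the component of the bottom-to-top direction orthogonal
to x, y = z × x.  With corners labelled as seen from outside the block,
y is the outward face normal; the frame construction needs no volume
thresholding.  For targeting, the block plane is fitted to the annotated
surface points and the corner clicks are projected onto it, so the
frame's orientation carries the (many-point) fitted plane's precision
rather than that of four individual clicks.

## Phantom generator

`microtarget.phantom` emulates a lab micro-CT scan of a trimmed resin
block: a trapezoidal prism (default face 120/90 µm wide × 100 µm high,
80 µm deep) at mid intensity (128) on a dark background (0), containing
bright ellipsoidal inclusions (200–255), voxelised at 1 µm isotropic
resolution into a 144³ grid by voxel-center membership (no
antialiasing), with optional additive Gaussian noise clipped to
[0, 255].  The default target lies 60 µm behind the face centroid at
offsets (−3.3°, 5.4°) with alignment (10°, 10°) — the worked-example
angles — and the face-to-target depth is within one feed length, the
geometry recommended for best accuracy.  Ground truth (corners, face
plane, target plane, offsets) is derived analytically from the
generating parameters, never from the rasterised image.

Annotation is emulated by sampling surface points uniformly over the
face quad and adding isotropic Gaussian jitter (manual point-placement
error); corner vertices and the target plane are copied exactly.

The simulated cut closes the loop physically rather than circularly: the
machine pose maps the *true* block frame to
W_B = Rx(θ_T)·Ry(θ_R)·Rx(−θ_IT)·Rz(θ_IK); the knife plane (vertical,
horizontal normal at θ_K) is mapped back into image coordinates through
B_true·W_Bᵀ and fed D_NS from the corner the knife actually touches
first.  Noise-free annotations reproduce the target plane to below
1e-9 (° and µm); 0.5 µm jitter stays below 0.5° and 2 µm over 50 seeds.
What the phantom does **not** model: CT physics (beam hardening, rings,
partial-volume blur), registration error between before/after scans,
knife-approach error at the block surface, mechanical backlash and
section compression.  Passing phantom tests therefore demonstrates the
correctness of the calculus and its error propagation from annotation
noise — not the instrument-level accuracy achievable on real samples,
which is dominated by exactly the unmodelled terms.

## Accuracy measures

- Angle error: arccos |n_target · n_after| ∈ [0°, 90°].  Absolute
  normals are used because fitted plane normals are sign-ambiguous.
- Solution distance error: D_P′/cos(θ_K) − D_Sol, where D_P′ is the
  perpendicular distance from the predicted first-touch point to the
  after surface.  Positive = over-trimmed.  Valid only if cutting really
  started at the predicted corner at the solution knife angle; the
  implementation warns when the after surface implies a different
  farthest corner.
- Point-to-plane error: |perpendicular distance| from a marked
  target-plane point to the after surface; depends on where the point
  was placed within the plane.
- Registration error: per-pair and mean Euclidean distance between
  matched fiducials.

## Problem sizes and runtime choices

The solution sweep evaluates 3,600 closed-form entries (0.1° grid) in
milliseconds (vectorised; the recorded verticality residual uses the
setup-constant form and is cross-checked against the full matrix product
in tests).  Phantom volumes default to 144³ voxels — large enough that
face, inclusions and target geometry are resolved at the 1 µm scan
resolution while keeping generation around a second.  The statistical
jitter tests use 50–100 seeds at 200 surface points, the point count a
careful annotator realistically places.

## Known limitations

- Image registration is out of scope: accuracy inputs must already be in
  the before-scan coordinate frame.
- Cross-section previews define their own deterministic in-plane basis
  (projected World x, fallback World y) and trilinear interpolation with
  zero fill; other viewers may render the same plane with a different
  in-plane rotation.
- The importer for externally produced annotation records is best-effort:
  unknown fields are preserved but the required field names follow this
  package's documented schema.
- Ellipsoidal inclusions are specified in block-local coordinates; there
  is no support for arbitrary meshes.
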