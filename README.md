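# microtarget

Targeted trimming of resin-embedded samples for volume electron
microscopy requires cutting a block to a *specific* plane chosen on a 3D
map — typically a lab micro-CT scan at ~1 µm isotropic voxel size.
`microtarget` turns plane and corner annotations on such a scan into the
three ultramicrotome solution angles (sample tilt, sample rotation,
knife tilt) and a cutting distance, predicts which structures will be
exposed at each cutting depth, and scores how accurately a finished run
hit its target.  Everything is testable without any instrument or real
scan via a built-in synthetic phantom generator with exact geometric
ground truth.

It is aimed at EM facility staff and developers of semi-automated
ultramicrotomy workflows who want the targeting calculus as a scriptable
library and CLI rather than embedded in a GUI.

## The calculus

World coordinates: x = east–west knife translation, y = north–south
cutting feed, z = vertical.  A targeting run is parameterised by four
constant angles: the initial sample tilt and knife tilt at manual
knife/block-face alignment (θ_IT, θ_IK; sample rotation is defined as
zero there), and the target offsets measured from the scan (θ_to about
the block frame's z, then θ_tr about the intermediate x).  The target
plane's orientation for machine angles (θ_T, θ_R) is the forward
kinematics product

    F = Rx(θ_T) · Ry(θ_R) · Rx(−θ_IT) · Rz(θ_IK) · Rz(θ_to) · Rx(θ_tr)

whose y column is the target normal in World coordinates.  A cut is
achievable when that normal is horizontal, (F·ŷ)·ẑ = 0, which yields a
one-parameter solution family: with the setup constants A–I (products of
sines/cosines of the four setup angles) and C1 = (−AF+G)/(−AI−H),
C2 = E/(−AI−H), C3 = AI+H, C4 = E, C5 = AF−G,

    θ_T(θ_R) = arctan( C1·cos θ_R + C2·sin θ_R )
    θ_K(θ_R) = arctan( C3·(C4·cos θ_R + C5·sin θ_R)
                       / ( sqrt(C3² + (C4·sin θ_R − C5·cos θ_R)²) · |C3| ) )

Solutions are feasible when |θ_T| ≤ 20° (the sample-tilt limit) and θ_K
is within the knife holder's range.  The distance solution measures the
perpendicular depth D_P from the target plane to the farthest block-face
corner (the first-touch point) and compensates the feed for the knife
tilt:

    D_NS = D_P / cos(θ_K)

Accuracy of a finished run is reported as the absolute angle between the
target and the re-scanned block surface, the signed solution-distance
error (positive = over-trimmed), and the point-to-plane distance from a
marked target point to the reached surface.

## Worked example

Generate a phantom scan (a 144³ µm trapezoidal resin block with bright
inclusions and a target plane 60 µm behind the face at offsets
(−3.3°, 5.4°)), measure the offsets, solve, and plan the cut:

```sh
$ microtarget phantom --out-volume phantom.tif --out-annotations annotations.json
phantom volume -> phantom.tif
annotations    -> annotations.json
ground truth offsets: theta_to=-3.3000 theta_tr=5.4000

$ microtarget offsets annotations.json
theta_to = -3.300000 deg
theta_tr = 5.400000 deg

$ microtarget solve annotations.json --theta-it 10 --theta-ik 10 --out solution.json
theta_to = -3.3000 deg, theta_tr = 5.4000 deg
3600/3600 grid solutions feasible
chosen solution: theta_R=-55.80 theta_T=8.0758 theta_K=-0.0038 (deg)
cut plan: D_P=67.284 µm, D_NS=67.284 µm, first touch top_right, resets 0
```

Reading: the annotated offsets are recovered exactly from the phantom;
every sample rotation on the 0.1° grid admits a solution within the axis
limits; the selected least-extreme pose tilts the sample 8.08° at a
rotation of −55.8° with an essentially untilted knife, so the 67.3 µm
perpendicular depth needs a 67.3 µm feed — well within one 200 µm feed
length, hence no mid-run reset.  `microtarget cut-preview` renders the
predicted cross-sections at chosen depths, and `microtarget accuracy`
scores a completed run from after-scan surface points.

The same pipeline is available as a library (`microtarget.kinematics`,
`.cutting`, `.accuracy`, `.phantom`, ...) for scripted use.

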