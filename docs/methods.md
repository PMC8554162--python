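# Methods

This note documents the measurement model implemented by `romvision`, the
numerical choices behind it, what the synthetic validation scenes do and do
not emulate, and the known limitations.

## Measurement model

**Imaging geometry.** Both cameras of the RGB-D device follow the pinhole
model with intrinsic matrix `K = [[fx, 0, u0], [0, fy, v0], [0, 0, 1]]`;
pixel coordinates are continuous with the origin at the top-left pixel
center, u along the image width. Lens distortion is Brown–Conrady on the
normalized (Z = 1) plane with radial coefficients `k1, k2, k3` and
tangential `p1, p2`. Distortion is inverted by fixed-point iteration
initialized at the distorted point (max 50 iterations, tolerance 1e-10 on
the forward-model residual); this converges for the mild distortion of
consumer RGB-D optics and raises a diagnostic error otherwise. Depth is
metric throughout — 16-bit millimeter files are converted to float meters
on read — because the extrinsic transform is metric and a single canonical
unit avoids silent scale bugs.

**Depth-to-color registration.** Each valid depth pixel is back-projected
through `K_d`, transformed by the rigid depth→color extrinsic `(R, t)`, and
forward-projected through `K_c`; the output map stores the color-frame Z at
the nearest color pixel. Colliding points resolve nearest-wins (z-buffer),
the physically correct occlusion rule; pixels receiving no point are
invalid (0). No hole-filling is performed — downstream sampling tolerates
sparse registration.

**Marker segmentation.** A pixel is marker iff its Euclidean RGB distance
to the role's reference color is ≤ T (inclusive; implemented as a
squared-distance comparison). Default T = 60 (8-bit units) and minimum
component size 40 px at 1280×720, chosen so that the strip colors used here
are recovered essentially completely under the default noise model while a
uniform background yields no false components; both are configuration
options. Components are 8-connected. Two role-tagging schemes exist:
distinct per-role reference colors (the default; each role segmented
independently, the largest component wins), or a single shared color with
nearest-centroid tracking seeded by an initial labeled frame and gated at
120 px. Tracking is stable as long as inter-marker image distance exceeds
per-frame marker motion, which the drag protocol guarantees at 30 fps.

**Depth-robust sampling.** A strip component is many pixels wide, but the
line fit wants one depth-bearing sample per location along the strip. The
component is partitioned into `bin_count` = 32 bins along its dominant
image axis (principal axis of the pixel coordinates). Each bin emits one
sample: the centroid of its valid-depth pixels (sub-pixel, which avoids
pixel-grid aliasing that otherwise imprints a sawtooth on the fitted
direction), carrying the *median* of the bin's valid depths. The median is
the method's only robustness device: it rejects depth speckle and
registration parallax at strip edges. `bin_count = 1` reproduces the
degenerate one-sample-per-marker reading; values ≥ 2 preserve the strip's
extent for line fitting.

**Fits.** All fits are orthogonal regression under a unit-norm constraint,
solved in closed form by eigendecomposition of the centered scatter matrix
(deterministic, no iterative optimization): plane normal = smallest
eigenvector; 3-D line direction = largest eigenvector, line through the
centroid; 2-D line `ax − by + c = 0` with `a² + b² = 1`, direction
`e = (b, a)`. Sign ambiguities are resolved canonically — plane: a > 0,
else b > 0, else c > 0; 3-D line: l > 0, else m > 0, else n > 0; 2-D line:
b ≥ 0, and a > 0 when b = 0. The strict-inequality conventions leave
measure-zero cases open; the lexicographic fallback closes them. Note the
2-D model's minus sign: only `ax − by + c` makes `(b, a)` a direction
vector of the line.

The 2-D sign convention constrains every fitted direction to the closed
right half-plane of the working frame, so sagittal angles are measured
modulo the ±180° strip ambiguity. The protocol keeps segment directions
within (−90°, 90°] of the seat axis, where the convention is unambiguous.

**Working frame.** The sagittal plane is fitted to calf samples pooled over
all calibration frames of a knee sweep (no weighting); the seat line is
fitted in the first frame where the seat strip is visible (the seat does
not move). The frame: x-axis = seat direction projected into the plane;
y-axis = normal × x-axis with the sign fixed so its image-down component is
non-negative — this makes the measured angle signs independent of the
plane-normal sign convention; z-axis by the right-hand rule; origin = seat
centroid projected onto the plane. A seat line more than 30° out of the
fitted plane is rejected as a configuration error.

**Angle series and ROM.** Sagittal per frame:
θ_k = signed∠(e_seat, e_thigh), θ_x = signed∠(e_thigh, e_calf), the sign
being that of the 2-D cross product (≥ 0 → positive). Coronal per frame: a
plane is fitted to pooled thigh+calf samples and
θ_kg = arccos |n_j · n_1| ∈ [0°, 90°] against the first frame's normal; the
protocol starts at abduction 0 with the knee bent, making frame 1 the
reference. A first-frame fit whose in-plane scatter ratio
(`sqrt(λ_mid/λ_max)`, the `planarity` diagnostic) falls below 0.06 is
rejected as degenerate: a straight knee leaves the leg plane undefined
(measured: ≈ 0.002 straight vs ≈ 0.14 at 45° flexion). Frames with a lost
marker or insufficient depth yield flagged missing values, never an abort;
ROM is the per-channel extrema over valid frames with the valid count
reported. The median-average filter (window 5, centered; drop the single
max and min, average the rest; truncated at edges; missing values excluded
and preserved) is applied to the coronal channel by protocol, optionally to
sagittal channels. Peak comparison detects prominence-filtered local
extrema in both traces (plateaus report their center) and matches maxima to
maxima / minima to minima greedily by nearest timestamp within a gate
(default 0.25 s).

## Synthetic scenes

The generator is the forward model of the chain: a two-link leg (thigh
0.40 m, calf 0.38 m) with 2 cm-wide strips along the segment axes (thigh
strip 0.25 m, calf 0.20 m, seat 0.25 m), offset 5 cm toward the camera like
tape on the side of a limb. The camera sits 1.2 m from the sagittal plane
(within the 0.8–1.5 m working range of the targeted close-range lidar
unit), 1280×720, fx = fy = 600 px, 30 fps, with a 2.5 cm depth-to-color
baseline so registration is genuinely exercised. Strips are rasterized by
dense surface point sampling (1.5 mm step, sub-pixel at the working
distance) with a global z-buffer; depth images are rendered in the
depth-camera geometry. Noise model: per-pixel Gaussian depth noise
(default σ = 5 mm, the sensor's stated accuracy at ~1 m), millimeter depth
quantization, optional dropout, and Gaussian 8-bit color noise (σ = 5). All
randomness flows from one integer seed; frames are regenerated
deterministically per (seed, frame index), so long sessions stream without
residing in memory.

Positive hip rotation is realized as rotation from the seat axis toward
image-down, positive knee rotation in the same in-plane sense from the
thigh extension, and abduction as rotation of the leg plane about the seat
axis through the hip — i.e. the camera views the side of the subject for
which the anatomical sign conventions (counterclockwise-positive hip,
clockwise-positive knee) coincide with the measured signs. Camera-placement
variation is modeled as a random rigid scene pose within a cone (±12°
rotations, ±5 cm translation, 1.0–1.4 m working distance): the protocol
requires the camera to roughly face the sagittal plane, and the canonical
sign conventions are only stable within such a cone.

What the scenes do **not** emulate: soft-tissue motion of markers taped to
skin, non-rigid strip deformation, lighting gradients and shadows
(segmentation sees additive Gaussian color noise only), occlusion by the
physician, rolling shutter, and correlated (non-white) depth error.
Passing tests therefore demonstrate correctness of the geometry and
estimation chain under the stated sensor model, not robustness to every
clinical artifact.

## Validation protocols and problem sizes

The replication of the precision experiment oscillates one segment while
the other is held: sagittal — knee 0–90° triangular, 6 cycles, 180 frames,
with the working frame built from a separate 16-frame noisy calibration
sweep; coronal — abduction 0–40° sinusoid, 6 cycles, 180 frames, knee bent
45°, filter window 5. Five seeds per plane. The reported statistic is the
maximum absolute matched-peak difference between the vision trace and the
generator's ground truth. Noiseless loop-closure testing uses 20 randomized
sessions per mode (10 frames each, random trajectories and scene poses)
and requires every per-frame angle within 0.5° at 1280×720 — the residual
error there is dominated by pixel quantization and rasterization.

## Limitations

* Single camera: out-of-sagittal-plane limb motion during a sagittal
  measurement biases projected angles (the projection model tolerates
  small out-of-plane marker offsets, not gross protocol violations).
* The coronal angle is unsigned ([0°, 90°]); abduction and adduction on
  opposite sides of the start plane are not distinguished.
* No robust fitting beyond median-depth sampling (no RANSAC); gross
  segmentation outliers would corrupt the fits, which is why distinct
  marker colors are the default.
* Intrinsics/extrinsics are inputs; the package does not calibrate the
  camera.
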