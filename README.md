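# romvision

Marker-based measurement of human lower-limb joint range of motion (ROM)
from a single RGB-D camera.

Before a rehabilitation robot can safely move a patient's leg, it needs the
patient's per-joint range of motion — the angular interval each joint may
traverse. The traditional instrument is a hand-held goniometer, which needs
two clinicians and is unreliable in the coronal plane. `romvision`
implements a machine-vision alternative: colored strip markers are placed
along the thigh, the calf, and the seat of the chair; a physician drags the
limb through its range while one RGB-D camera records; the software turns
the frame sequence into per-frame hip and knee angles and their extrema.

Measured quantities:

* **θ_k** — hip flexion/extension angle in the sagittal plane, zero at the
  seat-strip direction;
* **θ_x** — knee flexion angle in the sagittal plane, zero when thigh and
  calf are collinear;
* **θ_kg** — hip abduction angle in the coronal plane, zero at the starting
  leg-plane orientation, range [0°, 90°].

## Method

Each depth pixel `(u_d, v_d, z_d)` is lifted through the depth camera's
intrinsic matrix `K_d`, moved into the color camera frame by the device's
rigid extrinsic `(R, t)`, and re-projected through `K_c` (Brown–Conrady
distortion `k1, k2, k3, p1, p2` on the normalized plane), giving a depth
value for each color pixel. Markers are segmented by Euclidean RGB distance
to a reference color (`‖(R,G,B) − (R₁,G₁,B₁)‖ ≤ T`), grouped into connected
components, role-tagged, and reduced to depth-robust samples: the component
is binned along its dominant image axis and each bin contributes its pixel
centroid carrying the bin's median depth.

The sagittal working plane is fitted (orthogonal regression; the plane
normal is the smallest-eigenvalue eigenvector of the centered scatter
matrix) to calf samples pooled over a calibration knee sweep; the seat
strip's 3-D line defines the in-plane x-axis. Per frame, samples are lifted
to 3-D, projected into this plane, and each strip gets a constrained
total-least-squares line `ax − by + c = 0`, `a² + b² = 1`, with direction
`e = (b, a)`. Angles are signed by the 2-D cross product:

    θ_k = ±arccos(e_l · e_k),   sign(e_l × e_k)
    θ_x = ±arccos(e_k · e_x),   sign(e_k × e_x)

where `e_l, e_k, e_x` are the seat, thigh and calf directions. In the
coronal protocol the knee is bent and a plane is fitted per frame to the
pooled thigh+calf samples; `θ_kg = arccos |e_j · e_1|` against the first
frame's normal. A median-average filter (drop the window's extremes,
average the rest) suppresses impulse noise in the coronal trace. ROM is the
per-channel max/min over valid frames.

A synthetic scene generator renders a two-link leg with strip markers
through the same camera model (depth images natively in the depth-camera
geometry, configurable depth/color noise) and stores ground-truth angles,
providing the validation data for the whole chain.

## Worked example

Measure knee ROM on a simulated session (3 knee cycles, 0–90°, realistic
depth noise of 5 mm):

```python
import json
from romvision import *
from romvision.pipeline import build_reference_frame

noise = lambda s: NoiseSpec(depth_sigma=0.005, color_sigma=5.0, seed=s)

cal = generate_session("calibration", n_frames=16, noise=noise(11))
calib, seg = cal.calibration(), cal.segmentation()
frame_def = build_reference_frame(cal.rgbd_frames(), calib, seg)

sess = generate_session("sagittal-knee", n_frames=90, cycles=3, noise=noise(7))
series = compute_sagittal_series(sess.rgbd_frames(), calib, seg, frame_def)
print(json.dumps(extract_rom(series).to_dict(), indent=2))
```

prints

```
{
  "theta_k": {
    "max_deg": -9.920588682429774,
    "min_deg": -10.011886296339311,
    "frame_max": 74,
    "frame_min": 36,
    "n_valid_frames": 90
  },
  "theta_x": {
    "max_deg": 89.97048482114546,
    "min_deg": -0.04889263534690814,
    "frame_max": 15,
    "frame_min": 0,
    "n_valid_frames": 90
  }
}
```

The hip was held at −10° during the knee sweep and is recovered within
0.1°; the knee ROM spans the generated 0–90° sweep. Matching the vision
trace's peaks against the ground-truth trace
(`compare_with_reference(series.timestamps, series.theta_x, truth.time_s,
truth.theta_2_deg)`) reports 5 matched peaks with max |δ| = 0.060° for this
seed.

The same flow is available from the shell:

```
romvision simulate --mode sagittal-knee --frames 90 --cycles 3 --seed 7 --out knee/
romvision simulate --mode calibration --frames 16 --seed 11 --out cal/
romvision sagittal --frames knee/ --calibration-frames cal/ --out rom.json
```

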