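"""Replication protocols of the precision-verification experiments.

These functions reproduce, in simulation, the validation performed against
an angle-sensor-instrumented mechanical leg: one segment oscillates through
several cycles under realistic sensor noise, the vision pipeline measures
the angle trace, and corresponding peaks of the vision and ground-truth
traces are compared.  They are shared by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .pipeline import (
    PeakComparison,
    build_reference_frame,
    compare_with_reference,
    compute_coronal_series,
    compute_sagittal_series,
    median_average_filter,
)
from .synthetic import LegSceneConfig, NoiseSpec, TrajectorySpec, generate_session

__all__ = ["sagittal_peak_error", "coronal_peak_error", "VALIDATION_NOISE"]

#: sensor noise of the validation protocol: 5 mm depth accuracy at ~1 m,
#: millimeter depth quantization, mild 8-bit color noise
VALIDATION_NOISE = dict(depth_sigma=0.005, color_sigma=5.0, depth_quant=0.001)


def sagittal_peak_error(seed: int, n_frames: int = 180, cycles: int = 6,
                        cfg: LegSceneConfig | None = None) -> PeakComparison:
    """Peak-difference validation in the sagittal plane for one seed.

    The thigh is held still while the calf oscillates through ``cycles``
    triangular knee cycles spanning 0-90 degrees; the sagittal working frame
    is built from a separate (equally noisy) calibration sweep; vision knee
    peaks are matched to ground-truth peaks by nearest timestamp.
    """
    cfg = cfg or LegSceneConfig()
    cal = generate_session(
        "calibration", cfg=cfg,
        noise=NoiseSpec(seed=seed + 1000, **VALIDATION_NOISE), n_frames=16,
    )
    calib, seg = cal.calibration(), cal.segmentation()
    frame_def = build_reference_frame(cal.rgbd_frames(), calib, seg)
    sess = generate_session(
        "sagittal-knee", cfg=cfg, noise=NoiseSpec(seed=seed, **VALIDATION_NOISE),
        traj=TrajectorySpec.knee_sweep(n_frames, lo=0.0, hi=90.0, cycles=cycles),
    )
    series = compute_sagittal_series(sess.rgbd_frames(), calib, seg, frame_def)
    truth = sess.truth
    return compare_with_reference(
        series.timestamps, series.theta_x,
        truth.time_s.to_numpy(), truth.theta_2_deg.to_numpy(),
    )


def coronal_peak_error(seed: int, n_frames: int = 180, cycles: int = 6,
                       window: int = 5,
                       cfg: LegSceneConfig | None = None) -> PeakComparison:
    """Peak-difference validation in the coronal plane for one seed.

    Knee bent at 45 degrees, abduction oscillating 0-40 degrees; the vision
    trace is median-average filtered (window ``window``) before peak
    matching, as in the measurement protocol.
    """
    cfg = cfg or LegSceneConfig()
    sess = generate_session(
        "coronal", cfg=cfg, noise=NoiseSpec(seed=seed, **VALIDATION_NOISE),
        traj=TrajectorySpec.abduction_sweep(n_frames, knee=45.0, lo=0.0,
                                            hi=40.0, cycles=cycles),
    )
    series = compute_coronal_series(sess.rgbd_frames(), sess.calibration(),
                                    sess.segmentation())
    filtered = median_average_filter(series.theta_kg, window)
    truth = sess.truth
    return compare_with_reference(
        series.timestamps, filtered,
        truth.time_s.to_numpy(), truth.theta_h1_deg.to_numpy(),
    )
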