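"""Per-frame processing into joint-angle time series and ROM summaries.

The sagittal pipeline, per frame: segment the seat/thigh/calf strips, sample
depth-robust marker pixels, lift them to camera coordinates through the
calibration, project into the (pre-built) sagittal working frame, fit one
2-D line per strip, and form the hip angle as the signed angle from the seat
direction to the thigh direction and the knee angle as the signed angle from
the thigh to the calf direction.  The coronal pipeline fits a plane to the
pooled thigh+calf samples of each frame and measures the angle of its normal
against the first frame's normal (abduction starts at 0 by protocol).

Frames with a lost marker or insufficient depth yield flagged missing values
rather than aborting; ROM is taken over valid frames with the count
reported.  A median-average filter (drop the window extremes, average the
rest) suppresses impulse errors; by protocol it is applied to the coronal
channel before ROM extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .camera import Calibration, RGBDFrame, pixel_to_camera, register_depth_to_color
from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    EmptyInputError,
    InsufficientDepthError,
    NoValidDataError,
)
from .fitting import (
    SagittalFrame,
    build_sagittal_frame,
    fit_line_2d,
    fit_line_3d,
    fit_plane,
    plane_normal_angle,
    project_to_frame,
    signed_angle,
)
from .segmentation import LabeledMarker, SegmentationConfig, extract_labeled_markers

__all__ = [
    "JointAngleSeries",
    "ROMResult",
    "ChannelROM",
    "Peak",
    "build_reference_frame",
    "compute_sagittal_series",
    "compute_coronal_series",
    "median_average_filter",
    "extract_rom",
    "detect_peaks",
    "compare_with_reference",
]

_SAGITTAL_ROLES = ("seat", "thigh", "calf")
_CORONAL_ROLES = ("thigh", "calf")


@dataclass
class JointAngleSeries:
    """Per-frame joint angles in degrees (NaN = missing).

    Channels: ``theta_k`` hip sagittal, ``theta_x`` knee sagittal,
    ``theta_kg`` hip coronal.  ``flags`` holds per-frame quality notes
    (e.g. ``marker-lost:calf``).
    """

    timestamps: np.ndarray
    theta_k: np.ndarray | None = None
    theta_x: np.ndarray | None = None
    theta_kg: np.ndarray | None = None
    flags: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        for name in ("theta_k", "theta_x", "theta_kg"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ConfigurationError(f"channel {name} length mismatch")
        if not self.flags:
            self.flags = [() for _ in range(n)]

    def channels(self) -> dict[str, np.ndarray]:
        return {
            name: getattr(self, name)
            for name in ("theta_k", "theta_x", "theta_kg")
            if getattr(self, name) is not None
        }

    def to_dataframe(self) -> pd.DataFrame:
        data = {"frame": np.arange(len(self.timestamps)),
                "time_s": self.timestamps}
        for name, ch in self.channels().items():
            data[f"{name}_deg"] = ch
        data["flags"] = [";".join(f) for f in self.flags]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ChannelROM:
    max: float
    min: float
    argmax: int
    argmin: int
    n_valid: int


@dataclass(frozen=True)
class ROMResult:
    """Per-joint range of motion: channel name -> ChannelROM."""

    channels: dict[str, ChannelROM]

    def __getitem__(self, name: str) -> ChannelROM:
        return self.channels[name]

    def to_dict(self) -> dict:
        return {
            name: {"max_deg": c.max, "min_deg": c.min,
                   "frame_max": c.argmax, "frame_min": c.argmin,
                   "n_valid_frames": c.n_valid}
            for name, c in self.channels.items()
        }


def _lift_marker(marker: LabeledMarker, calib: Calibration) -> np.ndarray:
    """Marker (u, v, z) samples -> 3-D color-camera coordinates."""
    s = marker.samples
    return pixel_to_camera(s[:, 0], s[:, 1], s[:, 2], calib.color,
                           dist=calib.color_dist)


def build_reference_frame(frames: Iterable[RGBDFrame], calib: Calibration,
                          seg: SegmentationConfig,
                          prior=None) -> SagittalFrame:
    """Build the sagittal working frame from a calibration session.

    The knee is swept with the hip still; the calf marker samples of all
    calibration frames are pooled and plane-fitted (the sweep spans the
    sagittal plane), the seat strip of the first frame where it is visible
    is line-fitted as the zero reference, and the seat centroid (projected
    onto the plane) becomes the origin.
    """
    calf_points = []
    seat_line = None
    seat_centroid = None
    n = 0
    for frame in frames:
        n += 1
        reg = register_depth_to_color(frame.depth, calib)
        markers, _ = extract_labeled_markers(frame.color, reg, seg, prior=prior)
        if "calf" in markers:
            calf_points.append(_lift_marker(markers["calf"], calib))
        if seat_line is None and "seat" in markers:
            seat_pts = _lift_marker(markers["seat"], calib)
            seat_line = fit_line_3d(seat_pts)
            seat_centroid = seat_pts.mean(axis=0)
    if n == 0:
        raise EmptyInputError("no calibration frames")
    if not calf_points:
        raise InsufficientDepthError("no calf marker samples in calibration frames")
    if seat_line is None:
        raise InsufficientDepthError("seat marker never found in calibration frames")
    plane = fit_plane(np.concatenate(calf_points))
    return build_sagittal_frame(plane, seat_line, seat_centroid)


def compute_sagittal_series(frames: Iterable[RGBDFrame], calib: Calibration,
                            seg: SegmentationConfig, frame_def: SagittalFrame,
                            prior=None) -> JointAngleSeries:
    """Hip and knee sagittal angle series over a measurement session.

    Per frame, the seat / thigh / calf strip directions e_l, e_k, e_x are
    fitted in the working plane and the angles are
    theta_k = signed_angle(e_l, e_k), theta_x = signed_angle(e_k, e_x).
    Frames with a lost marker are flagged and yield NaN.
    """
    times, th_k, th_x, flags = [], [], [], []
    prior = dict(prior) if prior else None
    for frame in frames:
        reg = register_depth_to_color(frame.depth, calib)
        markers, missing = extract_labeled_markers(
            frame.color, reg, seg, prior=prior, roles=_SAGITTAL_ROLES,
            frame_index=frame.frame_index,
        )
        fr_flags = [f"marker-lost:{r}" for r in missing]
        dirs = {}
        for role in _SAGITTAL_ROLES:
            if role not in markers:
                continue
            pts3 = _lift_marker(markers[role], calib)
            pts2 = project_to_frame(pts3, frame_def)
            try:
                dirs[role] = fit_line_2d(pts2).direction
            except DegenerateGeometryError:
                fr_flags.append(f"degenerate:{role}")
        k = (signed_angle(dirs["seat"], dirs["thigh"])
             if "seat" in dirs and "thigh" in dirs else np.nan)
        x = (signed_angle(dirs["thigh"], dirs["calf"])
             if "thigh" in dirs and "calf" in dirs else np.nan)
        if prior is not None:
            for role, m in markers.items():
                prior[role] = m.samples[:, :2].mean(axis=0)
        times.append(frame.timestamp)
        th_k.append(k)
        th_x.append(x)
        flags.append(tuple(fr_flags))
    if not times:
        raise EmptyInputError("no frames to process")
    return JointAngleSeries(timestamps=np.asarray(times),
                            theta_k=np.asarray(th_k),
                            theta_x=np.asarray(th_x), flags=flags)


def compute_coronal_series(frames: Iterable[RGBDFrame], calib: Calibration,
                           seg: SegmentationConfig,
                           min_planarity: float = 0.06,
                           prior=None) -> JointAngleSeries:
    """Coronal hip (abduction) angle series.

    Per frame a plane is fitted to the pooled thigh+calf marker samples; the
    angle of its normal against the first frame's normal is the abduction
    angle (the protocol starts at 0 with the knee bent).  A first frame whose
    markers are nearly collinear (knee straight — plane undefined) raises
    :class:`DegenerateGeometryError`.
    """
    times, th_kg, flags = [], [], []
    ref_normal = None
    prior = dict(prior) if prior else None
    for frame in frames:
        reg = register_depth_to_color(frame.depth, calib)
        markers, missing = extract_labeled_markers(
            frame.color, reg, seg, prior=prior, roles=_CORONAL_ROLES,
            frame_index=frame.frame_index,
        )
        fr_flags = [f"marker-lost:{r}" for r in missing]
        angle = np.nan
        if all(r in markers for r in _CORONAL_ROLES):
            pts = np.concatenate(
                [_lift_marker(markers[r], calib) for r in _CORONAL_ROLES]
            )
            plane = fit_plane(pts)
            if plane.planarity < min_planarity:
                if ref_normal is None:
                    raise DegenerateGeometryError(
                        "thigh and calf markers are nearly collinear; bend "
                        "the knee to define the leg plane"
                    )
                fr_flags.append("degenerate:plane")
            else:
                if ref_normal is None:
                    ref_normal = plane.normal
                angle = plane_normal_angle(plane.normal, ref_normal)
        if prior is not None:
            for role, m in markers.items():
                prior[role] = m.samples[:, :2].mean(axis=0)
        times.append(frame.timestamp)
        th_kg.append(angle)
        flags.append(tuple(fr_flags))
    if not times:
        raise EmptyInputError("no frames to process")
    return JointAngleSeries(timestamps=np.asarray(times),
                            theta_kg=np.asarray(th_kg), flags=flags)


def median_average_filter(values: Sequence[float], window: int = 5) -> np.ndarray:
    """Sliding median-average filter.

    Centered window per sample; the window's single maximum and single
    minimum are dropped and the remaining values averaged.  Edges use the
    truncated window (still dropping extremes when >= 3 values remain, else
    a plain mean).  NaN values are excluded from windows and preserved in
    the output.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    x = np.asarray(values, dtype=float)
    if window > len(x):
        raise ConfigurationError("window exceeds series length")
    h = window // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        if not np.isfinite(x[i]):
            continue
        w = x[max(0, i - h): i + h + 1]
        w = w[np.isfinite(w)]
        if len(w) >= 3:
            w = np.sort(w)[1:-1]
        out[i] = w.mean()
    return out


def extract_rom(series: JointAngleSeries) -> ROMResult:
    """Per-channel max and min over valid samples, with attaining frames."""
    channels = {}
    for name, ch in series.channels().items():
        valid = np.isfinite(ch)
        if not np.any(valid):
            raise NoValidDataError(f"channel {name} has no valid samples")
        idx = np.nonzero(valid)[0]
        vals = ch[idx]
        channels[name] = ChannelROM(
            max=float(vals.max()), min=float(vals.min()),
            argmax=int(idx[np.argmax(vals)]), argmin=int(idx[np.argmin(vals)]),
            n_valid=int(valid.sum()),
        )
    return ROMResult(channels=channels)


@dataclass(frozen=True)
class Peak:
    index: int
    value: float
    kind: str  # "max" | "min"


def _interp_nan(x: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        raise NoValidDataError("series has no valid samples")
    out = x.copy()
    idx = np.arange(len(x))
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def detect_peaks(values: Sequence[float], min_prominence: float = 5.0
                 ) -> list[Peak]:
    """Local extrema with the given prominence, alternating max/min.

    Plateau peaks report their center sample.  Missing values are bridged by
    linear interpolation before detection.
    """
    x = _interp_nan(np.asarray(values, dtype=float))
    if len(x) < 3:
        raise EmptyInputError("need >= 3 samples for peak detection")
    peaks: list[Peak] = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        locs, props = find_peaks(sign * x, prominence=min_prominence,
                                 plateau_size=1)
        centers = (props["left_edges"] + props["right_edges"]) // 2
        peaks.extend(Peak(int(i), float(x[i]), kind) for i in centers)
    peaks.sort(key=lambda p: p.index)
    # enforce strict alternation: of adjacent same-kind peaks keep the extreme
    out: list[Peak] = []
    for p in peaks:
        if out and out[-1].kind == p.kind:
            better = (p.value > out[-1].value if p.kind == "max"
                      else p.value < out[-1].value)
            if better:
                out[-1] = p
        else:
            out.append(p)
    return out


@dataclass(frozen=True)
class PeakComparison:
    """Matched-peak differences between a vision trace and a reference."""

    deltas: list[tuple[float, float, str]]  # (time_s, vision - reference, kind)
    max_abs_delta: float
    n_vision_peaks: int
    n_reference_peaks: int


def compare_with_reference(vision_times, vision_values,
                           reference_times, reference_values,
                           min_prominence: float = 5.0,
                           time_gate: float = 0.25) -> PeakComparison:
    """Compare corresponding angle-trace peaks against a reference sensor.

    Peaks are detected in both traces, maxima matched to maxima and minima
    to minima greedily by nearest timestamp within ``time_gate`` seconds;
    each delta is vision minus reference.  An empty comparison (no matchable
    peaks) reports max |delta| = 0 with zero matches.
    """
    vt = np.asarray(vision_times, dtype=float)
    rt = np.asarray(reference_times, dtype=float)
    vp = detect_peaks(vision_values, min_prominence)
    rp = detect_peaks(reference_values, min_prominence)
    cands = []
    for i, p in enumerate(vp):
        for j, q in enumerate(rp):
            if p.kind != q.kind:
                continue
            dt = abs(vt[p.index] - rt[q.index])
            if dt <= time_gate:
                cands.append((dt, i, j))
    cands.sort(key=lambda c: c[0])
    used_v: set[int] = set()
    used_r: set[int] = set()
    deltas = []
    for dt, i, j in cands:
        if i in used_v or j in used_r:
            continue
        used_v.add(i)
        used_r.add(j)
        deltas.append((float(vt[vp[i].index]), vp[i].value - rp[j].value,
                       vp[i].kind))
    deltas.sort(key=lambda d: d[0])
    max_abs = max((abs(d[1]) for d in deltas), default=0.0)
    return PeakComparison(deltas=deltas, max_abs_delta=float(max_abs),
                          n_vision_peaks=len(vp), n_reference_peaks=len(rp))
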