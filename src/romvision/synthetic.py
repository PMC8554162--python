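"""Synthetic RGB-D scenes of a two-link leg with strip markers.

The generator is the forward model of the measurement chain: a seat-mounted
reference strip plus thigh and calf strips rigidly attached to an
articulated two-link leg are posed from ground-truth joint angles, rasterized
through the same pinhole + distortion + depth/color extrinsic model the
pipeline inverts, and corrupted with depth-sensor noise.  Every session
carries its ground-truth angle trace, so recovery error can be measured
exactly.

Scene conventions (before the optional rigid scene pose):

* The camera sits at the origin looking along +Z; the sagittal plane of the
  leg is parallel to the image plane at ``hip_position[2]`` meters.
* The seat strip runs along +X and is the zero reference of the hip angle.
* Positive hip angle rotates the thigh from +X toward +Y (image down);
  positive knee angle rotates the calf away from the thigh extension in the
  same in-plane sense; at knee angle 0 the thigh and calf strips are
  collinear.  This realizes the anatomical counterclockwise-positive hip /
  clockwise-positive knee conventions for a camera facing the appropriate
  side of the subject.
* Positive coronal hip angle (abduction) rotates the leg plane out of the
  sagittal plane about the seat axis through the hip.

Strips are offset from the segment axes along the leg-plane normal (toward
the camera), like tape on the side of a limb, and rendered by dense point
sampling with a z-buffer.  Depth images are produced in the depth-camera
geometry (nonzero depth-to-color extrinsic by default) so the registration
step is genuinely exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .camera import (
    Calibration,
    CameraIntrinsics,
    DistortionCoefficients,
    ExtrinsicRegistration,
    RGBDFrame,
    camera_to_pixel,
)
from .errors import GenerationError
from .segmentation import SegmentationConfig

__all__ = [
    "LegSceneConfig",
    "TrajectorySpec",
    "NoiseSpec",
    "StripPose",
    "pose_leg",
    "render_frame",
    "generate_session",
    "SyntheticSession",
    "random_scene_pose",
]


def _default_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=600.0, fy=600.0, u0=639.5, v0=359.5,
                            width=1280, height=720)


@dataclass(frozen=True)
class LegSceneConfig:
    """Geometry, optics and appearance of the synthetic scene.

    Lengths in meters.  Segment lengths follow adult anthropometry; strips
    are 2 cm-wide tape along the segment axes, offset ~5 cm toward the
    camera (the side of the limb).  The camera sits 1.2 m from the sagittal
    plane, inside the 0.8–1.5 m working range of a close-range lidar RGB-D
    unit, with a 2.5 cm depth-to-color baseline.
    """

    thigh_length: float = 0.40
    calf_length: float = 0.38
    thigh_strip_start: float = 0.10
    thigh_strip_length: float = 0.25
    calf_strip_start: float = 0.08
    calf_strip_length: float = 0.20
    seat_strip_length: float = 0.25
    strip_width: float = 0.02
    strip_offset: float = 0.05
    hip_position: tuple[float, float, float] = (-0.30, -0.10, 1.20)
    seat_strip_anchor: tuple[float, float, float] = (-0.72, -0.02, 1.20)
    role_colors: dict = field(default_factory=lambda: {
        "seat": (60, 200, 60),
        "thigh": (40, 60, 220),
        "calf": (220, 50, 50),
    })
    background_color: tuple[int, int, int] = (120, 120, 120)
    #: 0 = no depth return outside the scene content (beyond sensor range)
    background_depth: float = 0.0
    color_intrinsics: CameraIntrinsics = field(default_factory=_default_intrinsics)
    depth_intrinsics: CameraIntrinsics = field(default_factory=_default_intrinsics)
    color_dist: DistortionCoefficients = field(default_factory=DistortionCoefficients)
    depth_dist: DistortionCoefficients = field(default_factory=DistortionCoefficients)
    depth_to_color_t: tuple[float, float, float] = (0.025, 0.0, 0.0)
    depth_to_color_R: tuple = (1, 0, 0, 0, 1, 0, 0, 0, 1)
    fps: float = 30.0
    #: surface sampling step for rasterization (< one pixel footprint)
    sample_step: float = 0.0015
    #: optional rigid scene pose: rotation (row-major 9) about the hip plus
    #: a translation, emulating a different camera placement
    scene_rotation: tuple | None = None
    scene_translation: tuple[float, float, float] | None = None

    def calibration(self) -> Calibration:
        R = np.asarray(self.depth_to_color_R, dtype=float).reshape(3, 3)
        return Calibration(
            color=self.color_intrinsics,
            depth=self.depth_intrinsics,
            color_dist=self.color_dist,
            depth_dist=self.depth_dist,
            extrinsic=ExtrinsicRegistration(R=R, t=np.asarray(self.depth_to_color_t)),
        )

    def segmentation(self, **overrides) -> SegmentationConfig:
        return SegmentationConfig(role_colors=dict(self.role_colors), **overrides)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise model.

    Defaults match the close-range lidar unit the measurement targets:
    per-pixel Gaussian depth noise of 5 mm (the stated accuracy at ~1 m),
    millimeter depth quantization (16-bit millimeter storage), and mild
    8-bit color noise.
    """

    depth_sigma: float = 0.005
    color_sigma: float = 5.0
    depth_quant: float = 0.001
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_sigma < 0 or self.color_sigma < 0 or self.depth_quant < 0:
            raise GenerationError("noise magnitudes must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseSpec":
        return cls(depth_sigma=0.0, color_sigma=0.0, depth_quant=0.0,
                   dropout_prob=0.0, seed=seed)


def _triangular(n: int, lo: float, hi: float, cycles: float) -> np.ndarray:
    f = np.arange(n) * cycles / n % 1.0
    return lo + (hi - lo) * (1.0 - np.abs(2.0 * f - 1.0))


def _sinusoid(n: int, lo: float, hi: float, cycles: float) -> np.ndarray:
    f = np.arange(n) * cycles / n
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(2.0 * np.pi * f))


_WAVES = {"triangular": _triangular, "sinusoid": _sinusoid}


@dataclass(frozen=True)
class TrajectorySpec:
    """Per-frame ground-truth joint angles (degrees).

    ``theta_h2``: hip sagittal, ``theta_2``: knee, ``theta_h1``: hip coronal
    (abduction).  Constructors build the drag protocols of the measurement
    modes; custom arrays are accepted directly.
    """

    theta_h2: np.ndarray
    theta_2: np.ndarray
    theta_h1: np.ndarray

    def __post_init__(self) -> None:
        h2 = np.atleast_1d(np.asarray(self.theta_h2, dtype=float))
        t2 = np.atleast_1d(np.asarray(self.theta_2, dtype=float))
        h1 = np.atleast_1d(np.asarray(self.theta_h1, dtype=float))
        n = max(len(h2), len(t2), len(h1))
        bcast = lambda a: np.full(n, a[0]) if len(a) == 1 else a
        h2, t2, h1 = bcast(h2), bcast(t2), bcast(h1)
        if not (len(h2) == len(t2) == len(h1)):
            raise GenerationError("angle channels must share one length")
        object.__setattr__(self, "theta_h2", h2)
        object.__setattr__(self, "theta_2", t2)
        object.__setattr__(self, "theta_h1", h1)

    def __len__(self) -> int:
        return len(self.theta_h2)

    @classmethod
    def constant(cls, n: int, hip: float = 0.0, knee: float = 0.0,
                 abduction: float = 0.0) -> "TrajectorySpec":
        return cls(np.full(n, hip), np.full(n, knee), np.full(n, abduction))

    @classmethod
    def knee_sweep(cls, n: int, hip: float = -10.0, lo: float = 0.0,
                   hi: float = 90.0, cycles: float = 1.0,
                   wave: str = "triangular") -> "TrajectorySpec":
        """Knee drag with the hip held still (knee-ROM protocol)."""
        return cls(np.full(n, hip), _WAVES[wave](n, lo, hi, cycles), np.zeros(n))

    @classmethod
    def hip_sweep(cls, n: int, knee: float = 60.0, lo: float = -40.0,
                  hi: float = 20.0, cycles: float = 1.0,
                  wave: str = "triangular") -> "TrajectorySpec":
        """Hip drag in the sagittal plane (hip-ROM protocol)."""
        return cls(_WAVES[wave](n, lo, hi, cycles), np.full(n, knee), np.zeros(n))

    @classmethod
    def abduction_sweep(cls, n: int, knee: float = 45.0, hip: float = -10.0,
                        lo: float = 0.0, hi: float = 40.0, cycles: float = 1.0,
                        wave: str = "sinusoid") -> "TrajectorySpec":
        """Coronal drag: bent knee, abduction starting at 0."""
        return cls(np.full(n, hip), np.full(n, knee),
                   _WAVES[wave](n, lo, hi, cycles))

    @classmethod
    def calibration(cls, n: int = 16, hip: float = -10.0, lo: float = 10.0,
                    hi: float = 80.0) -> "TrajectorySpec":
        """Knee sweep used to fit the sagittal working plane."""
        return cls.knee_sweep(n, hip=hip, lo=lo, hi=hi, cycles=1.0)


@dataclass(frozen=True)
class StripPose:
    """A marker strip as a 3-D rectangle: centerline from p0 to p1, extended
    ±width/2 along width_dir."""

    p0: np.ndarray
    p1: np.ndarray
    width_dir: np.ndarray
    width: float


def _rot_x(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def pose_leg(angles_deg, cfg: LegSceneConfig) -> dict[str, StripPose]:
    """Pose the three marker strips for one frame.

    ``angles_deg`` is (theta_h2, theta_2, theta_h1).  The thigh rotates about
    the hip by the sagittal hip angle, the calf attaches at the knee rotated
    by the knee angle from the thigh extension, and the whole leg plane
    rotates out of the sagittal plane by the coronal (abduction) angle about
    the seat axis through the hip.
    """
    h2, t2, h1 = (math.radians(a) for a in angles_deg)
    hip = np.asarray(cfg.hip_position, dtype=float)
    rout = _rot_x(h1)
    d_thigh = rout @ np.array([math.cos(h2), math.sin(h2), 0.0])
    d_calf = rout @ np.array([math.cos(h2 + t2), math.sin(h2 + t2), 0.0])
    n_leg = rout @ np.array([0.0, 0.0, -1.0])
    knee = hip + cfg.thigh_length * d_thigh

    def strip(base, direction, start, length, normal):
        p0 = base + start * direction + cfg.strip_offset * normal
        p1 = p0 + length * direction
        wdir = np.cross(normal, direction)
        wdir = wdir / np.linalg.norm(wdir)
        return StripPose(p0=p0, p1=p1, width_dir=wdir, width=cfg.strip_width)

    seat_anchor = np.asarray(cfg.seat_strip_anchor, dtype=float)
    n_seat = np.array([0.0, 0.0, -1.0])
    strips = {
        "seat": strip(seat_anchor, np.array([1.0, 0.0, 0.0]), 0.0,
                      cfg.seat_strip_length, n_seat),
        "thigh": strip(hip, d_thigh, cfg.thigh_strip_start,
                       cfg.thigh_strip_length, n_leg),
        "calf": strip(knee, d_calf, cfg.calf_strip_start,
                      cfg.calf_strip_length, n_leg),
    }
    if cfg.scene_rotation is not None or cfg.scene_translation is not None:
        R = (np.asarray(cfg.scene_rotation, dtype=float).reshape(3, 3)
             if cfg.scene_rotation is not None else np.eye(3))
        t = (np.asarray(cfg.scene_translation, dtype=float)
             if cfg.scene_translation is not None else np.zeros(3))
        strips = {
            role: StripPose(
                p0=R @ (s.p0 - hip) + hip + t,
                p1=R @ (s.p1 - hip) + hip + t,
                width_dir=R @ s.width_dir,
                width=s.width,
            )
            for role, s in strips.items()
        }
    return strips


def _strip_points(s: StripPose, step: float) -> np.ndarray:
    length = float(np.linalg.norm(s.p1 - s.p0))
    d = (s.p1 - s.p0) / length
    n_len = max(int(math.ceil(length / step)) + 1, 2)
    n_wid = max(int(math.ceil(s.width / step)) + 1, 2)
    a = np.linspace(0.0, length, n_len)
    b = np.linspace(-s.width / 2.0, s.width / 2.0, n_wid)
    pts = (s.p0[None, None, :] + a[:, None, None] * d[None, None, :]
           + b[None, :, None] * s.width_dir[None, None, :])
    return pts.reshape(-1, 3)


def render_frame(strips: dict[str, StripPose], cfg: LegSceneConfig,
                 noise: NoiseSpec, rng: np.random.Generator,
                 timestamp: float = 0.0, frame_index: int = 0,
                 keep_labels: bool = False):
    """Rasterize one frame; returns (RGBDFrame, truth record).

    Color is rendered in the color-camera geometry (with its distortion);
    depth in the depth-camera geometry through the inverse extrinsic, then
    Gaussian noise, quantization and dropout are applied.  The truth record
    carries the strip centerline endpoints, per-strip visible fraction and
    (optionally) the per-pixel role label image.
    """
    kc, kd = cfg.color_intrinsics, cfg.depth_intrinsics
    calib = cfg.calibration()
    color = np.empty((kc.height, kc.width, 3), dtype=float)
    color[:] = np.asarray(cfg.background_color, dtype=float)
    labels = np.zeros((kc.height, kc.width), dtype=np.uint8)
    depth = np.full((kd.height, kd.width), np.inf)
    visibility: dict[str, float] = {}

    all_pts, all_ids = [], []
    for role_id, (role, s) in enumerate(strips.items(), start=1):
        pts = _strip_points(s, cfg.sample_step)
        all_pts.append(pts)
        all_ids.append(np.full(len(pts), role_id, dtype=np.uint8))
        u, v = camera_to_pixel(pts, kc, dist=cfg.color_dist)
        inb = ((u >= -0.5) & (u < kc.width - 0.5)
               & (v >= -0.5) & (v < kc.height - 0.5))
        visibility[role] = float(inb.mean())
    pts = np.concatenate(all_pts)
    ids = np.concatenate(all_ids)
    role_list = list(strips)
    palette = np.array(
        [cfg.background_color] + [cfg.role_colors[r] for r in role_list],
        dtype=float,
    )

    u, v = camera_to_pixel(pts, kc, dist=cfg.color_dist)
    ui = np.rint(u).astype(int)
    vi = np.rint(v).astype(int)
    inb = (ui >= 0) & (ui < kc.width) & (vi >= 0) & (vi < kc.height)
    # nearest-point-wins: draw far-to-near
    order = np.argsort(-pts[inb, 2], kind="stable")
    uo, vo = ui[inb][order], vi[inb][order]
    ido = ids[inb][order]
    color[vo, uo] = palette[ido]
    labels[vo, uo] = ido

    pts_d = (pts - calib.extrinsic.t) @ calib.extrinsic.R
    ud, vd = camera_to_pixel(pts_d, kd, dist=cfg.depth_dist)
    udi = np.rint(ud).astype(int)
    vdi = np.rint(vd).astype(int)
    inb_d = (udi >= 0) & (udi < kd.width) & (vdi >= 0) & (vdi < kd.height)
    np.minimum.at(depth, (vdi[inb_d], udi[inb_d]), pts_d[inb_d, 2])

    content = np.isfinite(depth)
    depth[~content] = cfg.background_depth
    valid = depth > 0
    if noise.depth_sigma > 0:
        depth[valid] += rng.normal(0.0, noise.depth_sigma, int(valid.sum()))
    if noise.depth_quant > 0:
        depth[valid] = np.round(depth[valid] / noise.depth_quant) * noise.depth_quant
    if noise.dropout_prob > 0:
        drop = rng.random(depth.shape) < noise.dropout_prob
        depth[drop] = 0.0
    depth[depth < 0] = 0.0

    if noise.color_sigma > 0:
        color += rng.normal(0.0, noise.color_sigma, color.shape)
    color = np.clip(np.rint(color), 0, 255).astype(np.uint8)

    truth = {
        "endpoints": {r: (s.p0.copy(), s.p1.copy()) for r, s in strips.items()},
        "visibility": visibility,
    }
    if keep_labels:
        truth["labels"] = labels
    frame = RGBDFrame(color=color, depth=depth, timestamp=timestamp,
                      frame_index=frame_index)
    return frame, truth


class SyntheticSession:
    """A lazily rendered ground-truth-annotated RGB-D sequence.

    Frames are regenerated deterministically from the seed on each
    iteration (per-frame child RNG keyed by (seed, frame index)), so a long
    session never needs to reside in memory.
    """

    def __init__(self, mode: str, traj: TrajectorySpec, cfg: LegSceneConfig,
                 noise: NoiseSpec, min_visible_fraction: float = 0.98):
        self.mode = mode
        self.traj = traj
        self.cfg = cfg
        self.noise = noise
        self.n_frames = len(traj)
        # cheap pre-check: centerline endpoints of every strip in every frame
        kc = cfg.color_intrinsics
        bad = 0
        for i in range(self.n_frames):
            strips = pose_leg(self._angles(i), cfg)
            ok = True
            for s in strips.values():
                for p in (s.p0, s.p1):
                    if p[2] <= 0:
                        ok = False
                        continue
                    u, v = camera_to_pixel(p, kc, dist=cfg.color_dist)
                    if not (0 <= u < kc.width and 0 <= v < kc.height):
                        ok = False
            bad += not ok
        if bad > (1.0 - min_visible_fraction) * self.n_frames:
            raise GenerationError(
                f"markers leave the image in {bad}/{self.n_frames} frames"
            )

    def _angles(self, i: int):
        return (self.traj.theta_h2[i], self.traj.theta_2[i], self.traj.theta_h1[i])

    def frames(self, keep_labels: bool = False):
        """Yield (RGBDFrame, truth record) pairs."""
        for i in range(self.n_frames):
            rng = np.random.default_rng([self.noise.seed, i])
            strips = pose_leg(self._angles(i), self.cfg)
            yield render_frame(strips, self.cfg, self.noise, rng,
                               timestamp=i / self.cfg.fps, frame_index=i,
                               keep_labels=keep_labels)

    def rgbd_frames(self):
        """Yield bare RGBDFrame objects (pipeline input)."""
        for frame, _ in self.frames():
            yield frame

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.cfg.fps

    @property
    def truth(self) -> pd.DataFrame:
        """Ground-truth angle trace as a data frame."""
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "time_s": self.timestamps,
            "theta_h2_deg": self.traj.theta_h2,
            "theta_2_deg": self.traj.theta_2,
            "theta_h1_deg": self.traj.theta_h1,
            "seed": self.noise.seed,
        })

    def calibration(self) -> Calibration:
        return self.cfg.calibration()

    def segmentation(self, **overrides) -> SegmentationConfig:
        return self.cfg.segmentation(**overrides)


_MODES = ("sagittal-hip", "sagittal-knee", "coronal", "calibration")


def generate_session(mode: str, traj: TrajectorySpec | None = None,
                     cfg: LegSceneConfig | None = None,
                     noise: NoiseSpec | None = None,
                     n_frames: int = 60, cycles: float = 1.0,
                     ) -> SyntheticSession:
    """Build a synthetic measurement session for one protocol mode.

    When ``traj`` is omitted, the mode's default drag protocol is generated
    (``n_frames`` frames, ``cycles`` oscillation cycles).  Coronal sessions
    start at abduction 0 with a bent knee; calibration sessions sweep the
    knee with the hip fixed for sagittal-plane fitting.
    """
    if mode not in _MODES:
        raise GenerationError(f"unknown mode '{mode}' (one of {_MODES})")
    cfg = cfg or LegSceneConfig()
    noise = noise or NoiseSpec.noiseless()
    if traj is None:
        if mode == "sagittal-knee":
            traj = TrajectorySpec.knee_sweep(n_frames, cycles=cycles)
        elif mode == "sagittal-hip":
            traj = TrajectorySpec.hip_sweep(n_frames, cycles=cycles)
        elif mode == "coronal":
            traj = TrajectorySpec.abduction_sweep(n_frames, cycles=cycles)
        else:
            traj = TrajectorySpec.calibration(n_frames)
    if mode == "coronal" and abs(traj.theta_h1[0]) > 1e-9:
        raise GenerationError("coronal sessions must start at abduction 0")
    return SyntheticSession(mode, traj, cfg, noise)


def random_scene_pose(cfg: LegSceneConfig, rng: np.random.Generator,
                      max_angle_deg: float = 12.0,
                      max_shift: float = 0.05,
                      depth_range: tuple[float, float] = (1.0, 1.4)
                      ) -> LegSceneConfig:
    """Perturb the camera placement by a random rigid scene pose.

    Rotations are drawn within a cone (the protocol requires the camera to
    roughly face the sagittal plane) and the working distance within the
    sensor's recommended range.
    """
    angles = np.radians(rng.uniform(-max_angle_deg, max_angle_deg, size=3))
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    shift = rng.uniform(-max_shift, max_shift, size=3)
    z0 = rng.uniform(*depth_range)
    shift[2] += z0 - cfg.hip_position[2]
    return replace(cfg, scene_rotation=tuple(R.ravel()),
                   scene_translation=tuple(shift))
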