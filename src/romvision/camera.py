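"""Pinhole camera model, lens distortion, and depth-to-color registration.

An RGB-D device carries two cameras: a depth sensor and a color sensor with
distinct intrinsics and a fixed rigid transform between them.  This module
implements the forward/backward projection through the intrinsic matrix

    K = [[fx, 0, u0], [0, fy, v0], [0, 0, 1]],

the Brown–Conrady distortion model with radial coefficients (k1, k2, k3) and
tangential coefficients (p1, p2) applied on the normalized (Z = 1) plane, and
the re-projection of every depth pixel into the color image geometry so that
each color pixel can be annotated with a metric depth.

Conventions
-----------
* Pixel coordinates (u, v) are continuous, origin at the top-left pixel
  center, u along image width, v along height.
* Depth is metric (meters, float); 0 or NaN marks an invalid pixel.
* Camera coordinates: X right, Y down, Z forward (right-handed).

All point-wise operations broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BehindCameraError,
    ConfigurationError,
    ConvergenceError,
    InvalidDepthError,
)

__all__ = [
    "CameraIntrinsics",
    "DistortionCoefficients",
    "ExtrinsicRegistration",
    "Calibration",
    "RGBDFrame",
    "pixel_to_camera",
    "camera_to_pixel",
    "apply_distortion",
    "undistort",
    "register_depth_to_color",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Intrinsic parameters of one pinhole camera.

    fx, fy are the focal length times the pixel scale along u and v (pixels);
    (u0, v0) is the principal point (pixels).
    """

    fx: float
    fy: float
    u0: float
    v0: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ConfigurationError("focal lengths must be positive")
        if not (0 <= self.u0 < self.width and 0 <= self.v0 < self.height):
            raise ConfigurationError("principal point outside the image")

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 intrinsic matrix K."""
        return np.array(
            [[self.fx, 0.0, self.u0], [0.0, self.fy, self.v0], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class DistortionCoefficients:
    """Radial (k1, k2, k3) and tangential (p1, p2) distortion coefficients.

    All-zero coefficients give the identity model.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.k3, self.p1, self.p2)
        if not all(np.isfinite(v) for v in vals):
            raise ConfigurationError("distortion coefficients must be finite")

    @property
    def is_identity(self) -> bool:
        return self.k1 == self.k2 == self.k3 == self.p1 == self.p2 == 0.0


@dataclass(frozen=True)
class ExtrinsicRegistration:
    """Rigid transform mapping depth-camera coordinates into color-camera
    coordinates: X_color = R @ X_depth + t (t in meters)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ConfigurationError("R is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ConfigurationError("R is not a proper rotation (det != 1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "ExtrinsicRegistration":
        return cls(R=np.eye(3), t=np.zeros(3))


@dataclass(frozen=True)
class Calibration:
    """Full calibration of an RGB-D device: intrinsics and distortion of both
    cameras plus the depth-to-color extrinsic."""

    color: CameraIntrinsics
    depth: CameraIntrinsics
    color_dist: DistortionCoefficients = field(default_factory=DistortionCoefficients)
    depth_dist: DistortionCoefficients = field(default_factory=DistortionCoefficients)
    extrinsic: ExtrinsicRegistration = field(
        default_factory=ExtrinsicRegistration.identity
    )


@dataclass
class RGBDFrame:
    """One timestamped color image plus per-pixel metric depth.

    ``color`` is H x W x 3 uint8 RGB; ``depth`` is H x W float meters in the
    DEPTH camera geometry (register to the color geometry before per-pixel
    pairing).  0 or NaN depth marks an invalid pixel.
    """

    color: np.ndarray
    depth: np.ndarray
    timestamp: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.color = np.asarray(self.color)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise ConfigurationError("color image must be H x W x 3")
        if self.depth.ndim != 2:
            raise ConfigurationError("depth image must be H x W")
        valid = np.isfinite(self.depth) & (self.depth != 0)
        if np.any(self.depth[valid] < 0):
            raise InvalidDepthError("negative depth values present")


def pixel_to_camera(u, v, z, intr: CameraIntrinsics,
                    dist: DistortionCoefficients | None = None) -> np.ndarray:
    """Back-project pixel coordinates with metric depth to camera coordinates.

    Parameters broadcast; returns an array of shape (..., 3).  When ``dist``
    is given, the pixel is taken from a distorted image: the normalized
    coordinates are undistorted before scaling by depth.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)) or np.any(z <= 0):
        raise InvalidDepthError("depth must be finite and > 0")
    x = (u - intr.u0) / intr.fx
    y = (v - intr.v0) / intr.fy
    if dist is not None and not dist.is_identity:
        x, y = undistort(x, y, dist)
    return np.stack([x * z, y * z, z], axis=-1)


def camera_to_pixel(point, intr: CameraIntrinsics,
                    dist: DistortionCoefficients | None = None):
    """Project camera-frame points (..., 3) to continuous pixel coordinates.

    No clipping to image bounds is performed.  When ``dist`` is given the
    distortion model is applied on the normalized plane before pixel scaling.
    """
    point = np.asarray(point, dtype=float)
    X, Y, Z = point[..., 0], point[..., 1], point[..., 2]
    if np.any(Z <= 0):
        raise BehindCameraError("point(s) with Z <= 0 cannot be projected")
    x = X / Z
    y = Y / Z
    if dist is not None and not dist.is_identity:
        x, y = apply_distortion(x, y, dist)
    u = intr.fx * x + intr.u0
    v = intr.fy * y + intr.v0
    return u, v


def apply_distortion(x, y, d: DistortionCoefficients):
    """Forward Brown–Conrady distortion on normalized coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    radial = 1.0 + d.k1 * r2 + d.k2 * r2 * r2 + d.k3 * r2 * r2 * r2
    x_d = x * radial + 2.0 * d.p1 * x * y + d.p2 * (r2 + 2.0 * x * x)
    y_d = y * radial + 2.0 * d.p2 * x * y + d.p1 * (r2 + 2.0 * y * y)
    return x_d, y_d


def undistort(x_d, y_d, d: DistortionCoefficients,
              tol: float = 1e-10, max_iter: int = 50):
    """Invert the distortion model by fixed-point iteration.

    Initialized at the distorted point; converges for the mild distortion of
    consumer RGB-D optics.  Raises :class:`ConvergenceError` (reporting the
    worst residual) if the forward-model residual stays above ``tol`` after
    ``max_iter`` iterations.
    """
    x_d = np.asarray(x_d, dtype=float)
    y_d = np.asarray(y_d, dtype=float)
    if d.is_identity:
        return x_d.copy(), y_d.copy()
    x, y = x_d.copy(), y_d.copy()
    for _ in range(max_iter):
        r2 = x * x + y * y
        radial = 1.0 + d.k1 * r2 + d.k2 * r2 * r2 + d.k3 * r2 * r2 * r2
        dx_t = 2.0 * d.p1 * x * y + d.p2 * (r2 + 2.0 * x * x)
        dy_t = 2.0 * d.p2 * x * y + d.p1 * (r2 + 2.0 * y * y)
        x = (x_d - dx_t) / radial
        y = (y_d - dy_t) / radial
        fx, fy = apply_distortion(x, y, d)
        res = np.max(np.hypot(fx - x_d, fy - y_d))
        if res < tol:
            return x, y
    raise ConvergenceError(
        f"undistortion did not converge (residual {res:.3e})", residual=float(res)
    )


def register_depth_to_color(depth: np.ndarray, calib: Calibration) -> np.ndarray:
    """Re-project a depth image into the color camera geometry.

    Each valid depth pixel is back-projected through the depth intrinsics,
    transformed by the depth→color extrinsic, and forward-projected through
    the color intrinsics.  The returned map (color image size, float meters)
    holds the color-frame Z of the transformed point at the nearest pixel;
    colliding points are resolved nearest-wins (z-buffer); pixels receiving
    no point hold 0 (invalid).
    """
    depth = np.asarray(depth, dtype=float)
    kd, kc = calib.depth, calib.color
    if depth.shape != (kd.height, kd.width):
        raise ConfigurationError(
            f"depth image shape {depth.shape} does not match depth intrinsics "
            f"({kd.height}, {kd.width})"
        )
    valid = np.isfinite(depth) & (depth > 0)
    out = np.full((kc.height, kc.width), np.inf)
    if np.any(valid):
        vv, uu = np.nonzero(valid)
        z = depth[vv, uu]
        pts = pixel_to_camera(uu.astype(float), vv.astype(float), z, kd,
                              dist=calib.depth_dist)
        pts = pts @ calib.extrinsic.R.T + calib.extrinsic.t
        front = pts[:, 2] > 0
        pts = pts[front]
        if len(pts):
            u, v = camera_to_pixel(pts, kc, dist=calib.color_dist)
            ui = np.rint(u).astype(int)
            vi = np.rint(v).astype(int)
            inb = (ui >= 0) & (ui < kc.width) & (vi >= 0) & (vi < kc.height)
            np.minimum.at(out, (vi[inb], ui[inb]), pts[inb, 2])
    out[~np.isfinite(out)] = 0.0
    return out
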