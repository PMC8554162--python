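"""Constrained total-least-squares fits and joint-angle formulas.

Planes and lines are fitted by orthogonal regression: minimize the sum of
squared perpendicular distances subject to a unit-norm constraint on the
normal / direction vector.  Both problems reduce to an eigendecomposition of
the centered scatter matrix — the normal of the best plane is the eigenvector
with the smallest eigenvalue, the direction of the best line the one with the
largest.  Closed-form eigen solutions are used (no iterative optimization)
for determinism.

Sign conventions resolve the inherent +/- ambiguity of normals and
directions: the first nonzero component in a fixed component order is made
positive (plane normal: a, then b, then c; 3-D line: l, m, n; 2-D line:
b >= 0, falling back to a > 0).  Exact-zero leading components fall through
lexicographically, so every fit has one canonical representative.

Angles are reported in degrees.  The sagittal-plane joint angles are signed
via the 2-D cross product of the reference and target direction vectors; the
coronal hip angle is the unsigned angle between plane normals, folded to
[0, 90] by taking the absolute dot product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ConfigurationError, RomVisionError

__all__ = [
    "FittedPlane",
    "FittedLine3D",
    "FittedLine2D",
    "SagittalFrame",
    "fit_plane",
    "fit_line_3d",
    "fit_line_2d",
    "build_sagittal_frame",
    "project_to_frame",
    "signed_angle",
    "plane_normal_angle",
]

_EPS = 1e-12


def _canonical_sign(vec: np.ndarray) -> np.ndarray:
    """Flip ``vec`` so its first component with |x| > eps is positive."""
    for c in vec:
        if abs(c) > _EPS:
            return vec if c > 0 else -vec
    return vec


@dataclass(frozen=True)
class FittedPlane:
    """Plane a·x + b·y + c·z + d = 0 with unit normal (a, b, c)."""

    a: float
    b: float
    c: float
    d: float
    rms_residual: float = 0.0
    #: sqrt ratio of mid to max eigenvalue of the in-plane scatter; a
    #: conditioning diagnostic (near 0 = the points are nearly collinear).
    planarity: float = 1.0

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def signed_distance(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.normal + self.d

    def project(self, points) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        points = np.asarray(points, dtype=float)
        return points - np.outer(self.signed_distance(points), self.normal).reshape(
            points.shape
        )


@dataclass(frozen=True)
class FittedLine3D:
    """3-D line through ``centroid`` with unit ``direction``."""

    centroid: np.ndarray
    direction: np.ndarray
    rms_residual: float = 0.0


@dataclass(frozen=True)
class FittedLine2D:
    """2-D line a·x − b·y + c = 0 with a² + b² = 1; direction e = (b, a)."""

    a: float
    b: float
    c: float
    rms_residual: float = 0.0

    @property
    def direction(self) -> np.ndarray:
        return np.array([self.b, self.a])


@dataclass(frozen=True)
class SagittalFrame:
    """Orthonormal working frame of the sagittal plane.

    ``x_axis`` follows the seat reference strip (zero reference of the hip
    angle), ``y_axis`` lies in the plane with a non-negative image-down
    component, ``z_axis`` completes a right-handed triad.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


def _scatter_eig(points: np.ndarray):
    """Eigendecomposition (ascending) of the centered scatter matrix."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    scatter = centered.T @ centered
    evals, evecs = np.linalg.eigh(scatter)
    return centroid, centered, evals, evecs


def fit_plane(points) -> FittedPlane:
    """Orthogonal-regression plane fit.

    Minimizes sum((a·xi + b·yi + c·zi + d)²) subject to a² + b² + c² = 1: the
    normal is the smallest-eigenvalue eigenvector of the centered scatter
    matrix and d = −normal · centroid.  Requires >= 3 non-collinear points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 3-D points")
    centroid, centered, evals, evecs = _scatter_eig(points)
    # collinear iff the two smallest eigenvalues both (near-)vanish relative
    # to the spread
    if evals[1] <= _EPS * max(evals[2], _EPS):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    normal = _canonical_sign(evecs[:, 0])
    d = -float(normal @ centroid)
    rms = float(np.sqrt(max(evals[0], 0.0) / len(points)))
    planarity = float(np.sqrt(max(evals[1], 0.0) / max(evals[2], _EPS)))
    return FittedPlane(*normal, d, rms_residual=rms, planarity=planarity)


def fit_line_3d(points) -> FittedLine3D:
    """Orthogonal-regression 3-D line fit.

    The line passes through the centroid; its direction is the
    largest-eigenvalue eigenvector of the centered scatter matrix (the
    principal axis), which minimizes the summed squared perpendicular
    distances.  Requires >= 2 distinct points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
        raise DegenerateGeometryError("line fit needs >= 2 3-D points")
    centroid, centered, evals, evecs = _scatter_eig(points)
    if evals[2] <= _EPS:
        raise DegenerateGeometryError("all points identical; line undefined")
    direction = _canonical_sign(evecs[:, 2])
    rms = float(np.sqrt(max(evals[0] + evals[1], 0.0) / len(points)))
    return FittedLine3D(centroid=centroid, direction=direction, rms_residual=rms)


def fit_line_2d(points) -> FittedLine2D:
    """Constrained 2-D line fit: minimize sum((a·xi − b·yi + c)²), a² + b² = 1.

    With c eliminated at the centroid, (a, −b) is the smallest-eigenvalue
    eigenvector of the 2-D centered scatter matrix; the direction vector of
    the line is e = (b, a).  Sign convention: b >= 0, and a > 0 when b = 0.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 2:
        raise DegenerateGeometryError("line fit needs >= 2 2-D points")
    centroid, centered, evals, evecs = _scatter_eig(points)
    if evals[1] <= _EPS:
        raise DegenerateGeometryError("all points identical; line undefined")
    a, neg_b = evecs[:, 0]
    b = -neg_b
    if b < 0 or (b == 0 and a < 0):
        a, b = -a, -b
    # guard measure-zero b == -0.0 after flip
    if b == 0:
        b = 0.0
        a = abs(a)
    c = -(a * centroid[0] - b * centroid[1])
    rms = float(np.sqrt(max(evals[0], 0.0) / len(points)))
    return FittedLine2D(a=float(a), b=float(b), c=float(c), rms_residual=rms)


def build_sagittal_frame(plane: FittedPlane, seat_line: FittedLine3D,
                         origin_hint, max_line_plane_angle: float = 30.0
                         ) -> SagittalFrame:
    """Construct the 2-D working frame from the fitted sagittal plane and the
    seat reference line.

    The x-axis is the seat-line direction projected into the plane and
    renormalized; the y-axis is plane-normal × x-axis with its sign chosen so
    the second (image-down) component is non-negative; the z-axis completes
    the right-hand rule.  The origin is ``origin_hint`` projected orthogonally
    onto the plane.  The seat line must make less than
    ``max_line_plane_angle`` degrees with the plane.
    """
    n = plane.normal
    d = seat_line.direction
    out_of_plane = float(np.clip(abs(d @ n), -1.0, 1.0))
    if np.degrees(np.arcsin(out_of_plane)) >= max_line_plane_angle:
        raise ConfigurationError(
            "seat line is too far out of the fitted plane "
            f"({np.degrees(np.arcsin(out_of_plane)):.1f} deg)"
        )
    x_axis = d - (d @ n) * n
    x_axis = x_axis / np.linalg.norm(x_axis)
    y_axis = np.cross(n, x_axis)
    if y_axis[1] < 0:
        y_axis = -y_axis
    z_axis = np.cross(x_axis, y_axis)
    origin = plane.project(np.asarray(origin_hint, dtype=float))
    return SagittalFrame(origin=origin, x_axis=x_axis, y_axis=y_axis,
                         z_axis=z_axis)


def project_to_frame(points, frame: SagittalFrame) -> np.ndarray:
    """Orthogonally project 3-D points into the frame plane; return (x, y)."""
    points = np.asarray(points, dtype=float)
    rel = points - frame.origin
    x = rel @ frame.x_axis
    y = rel @ frame.y_axis
    return np.stack([x, y], axis=-1)


def signed_angle(e_ref, e_tgt) -> float:
    """Signed angle (degrees, (−180, 180]) from ``e_ref`` to ``e_tgt``.

    Magnitude is arccos of the normalized dot product; the sign is the sign
    of the scalar cross product e_ref × e_tgt, with cross >= 0 mapping to a
    positive angle.
    """
    e_ref = np.asarray(e_ref, dtype=float)
    e_tgt = np.asarray(e_tgt, dtype=float)
    nr = np.linalg.norm(e_ref)
    nt = np.linalg.norm(e_tgt)
    if nr <= _EPS or nt <= _EPS:
        raise RomVisionError("zero vector passed to signed_angle")
    cosang = np.clip(e_ref @ e_tgt / (nr * nt), -1.0, 1.0)
    ang = float(np.degrees(np.arccos(cosang)))
    cross = e_ref[0] * e_tgt[1] - e_ref[1] * e_tgt[0]
    return ang if cross >= 0 else -ang


def plane_normal_angle(n_j, n_ref) -> float:
    """Unsigned angle (degrees, [0, 90]) between two plane normals.

    Uses the absolute dot product so antipodal normals describe the same
    plane (angle 0).
    """
    n_j = np.asarray(n_j, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    nj = np.linalg.norm(n_j)
    nr = np.linalg.norm(n_ref)
    if nj <= _EPS or nr <= _EPS:
        raise RomVisionError("zero vector passed to plane_normal_angle")
    cosang = np.clip(abs(n_j @ n_ref) / (nj * nr), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
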