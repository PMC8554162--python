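"""Total-least-squares fits, the sagittal working frame, and angle formulas.

Fits are checked against independent SVD/eigendecomposition oracles and for
invariance to point ordering and equivariance under rigid motion.
"""

import numpy as np
import pytest

from romvision.errors import ConfigurationError, DegenerateGeometryError, RomVisionError
from romvision.fitting import (
    build_sagittal_frame,
    fit_line_2d,
    fit_line_3d,
    fit_plane,
    plane_normal_angle,
    project_to_frame,
    signed_angle,
)


def svd_plane_normal(points):
    """Oracle: plane normal = left singular vector of the smallest singular
    value of the centered coordinate matrix."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def svd_line_direction(points):
    """Oracle: line direction = principal right singular vector."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def align(v, ref):
    return v if v @ ref >= 0 else -v


class TestFitPlane:
    def test_exact_plane_x_equals_1(self):
        pts = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=float)
        p = fit_plane(pts)
        np.testing.assert_allclose([p.a, p.b, p.c, p.d], [1, 0, 0, -1], atol=1e-12)

    def test_sign_tie_break_z_plane(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, 200), rng.uniform(-1, 1, 200),
                               np.zeros(200)])
        p = fit_plane(pts)
        # a = b = 0 falls through to the c > 0 branch
        np.testing.assert_allclose([p.a, p.b, p.c, p.d], [0, 0, 1, 0], atol=1e-12)

    def test_noisy_plane_matches_svd_oracle(self, rng):
        for _ in range(20):
            n = align(rng.normal(size=3), np.array([1.0, 0.1, 0.1]))
            n /= np.linalg.norm(n)
            basis = np.linalg.svd(n[None, :])[2][1:]
            coef = rng.uniform(-1, 1, (500, 2))
            pts = coef @ basis + rng.uniform(-1, 1, 3)
            pts += rng.normal(0, 1e-3, pts.shape)
            p = fit_plane(pts)
            oracle = align(svd_plane_normal(pts), p.normal)
            np.testing.assert_allclose(p.normal, oracle, atol=1e-9)
            angle = np.degrees(np.arccos(np.clip(abs(p.normal @ n), 0, 1)))
            assert angle < 0.2

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5, dtype=float), [1, 2, 3])
        with pytest.raises(DegenerateGeometryError):
            fit_plane(pts)

    def test_order_invariance_and_equivariance(self, rng):
        pts = rng.normal(size=(50, 3))
        pts[:, 2] *= 0.01
        p1 = fit_plane(pts)
        p2 = fit_plane(pts[::-1])
        np.testing.assert_allclose(p1.normal, p2.normal, atol=1e-12)
        # rigid motion
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(size=3)
        p3 = fit_plane(pts @ q.T + t)
        np.testing.assert_allclose(
            align(p3.normal, q @ p1.normal), q @ p1.normal, atol=1e-9
        )


class TestFitLine3D:
    def test_exact_diagonal_line(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=float)
        line = fit_line_3d(pts)
        np.testing.assert_allclose(line.centroid, [1, 1, 1])
        np.testing.assert_allclose(line.direction, np.ones(3) / np.sqrt(3))

    def test_y_axis_tie_break(self):
        pts = np.column_stack([np.zeros(5), np.arange(5.0), np.zeros(5)])
        line = fit_line_3d(pts)
        np.testing.assert_allclose(line.direction, [0, 1, 0], atol=1e-12)

    def test_noisy_line_matches_pca_oracle(self, rng):
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            t = rng.uniform(-1, 1, 300)
            pts = np.outer(t, d) + rng.uniform(-1, 1, 3)
            pts += rng.normal(0, 1e-3, pts.shape)
            line = fit_line_3d(pts)
            oracle = align(svd_line_direction(pts), line.direction)
            np.testing.assert_allclose(line.direction, oracle, atol=1e-9)
            angle = np.degrees(np.arccos(np.clip(abs(line.direction @ d), 0, 1)))
            assert angle < 0.2

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_line_3d(np.ones((4, 3)))


class TestFitLine2D:
    def test_diagonal(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        e = fit_line_2d(pts).direction
        np.testing.assert_allclose(e, [np.sqrt(2) / 2, np.sqrt(2) / 2], atol=1e-12)

    def test_vertical_tie_break(self):
        pts = np.array([[0, 0], [0, 1], [0, 2]], dtype=float)
        np.testing.assert_allclose(fit_line_2d(pts).direction, [0, 1], atol=1e-12)

    def test_horizontal(self):
        pts = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        np.testing.assert_allclose(fit_line_2d(pts).direction, [1, 0], atol=1e-12)

    def test_direction_lies_on_fitted_line(self, rng):
        # a(x) - b(y) + c = 0 must hold along centroid + s * e
        pts = rng.normal(size=(40, 2)) * [2.0, 0.05] + [3.0, -1.0]
        f = fit_line_2d(pts)
        c0 = pts.mean(axis=0)
        for s in (-1.0, 1.0):
            p = c0 + s * f.direction
            assert abs(f.a * p[0] - f.b * p[1] + f.c) < 1e-9

    def test_tls_matches_svd_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 2))
            if np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
                continue
            f = fit_line_2d(pts)
            centered = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(centered)
            oracle = align(vt[0], f.direction)
            np.testing.assert_allclose(f.direction, oracle, atol=1e-9)


class TestSagittalFrame:
    def test_hand_construction(self):
        plane = fit_plane(np.array([[0, 0, 1], [1, 0, 1], [0, 1, 1], [2, 3, 1]],
                                   dtype=float))
        seat = fit_line_3d(np.array([[0, 0, 1], [1, 0, 1]], dtype=float))
        fr = build_sagittal_frame(plane, seat, np.zeros(3))
        np.testing.assert_allclose(fr.origin, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(fr.x_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.y_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fr.z_axis, [0, 0, 1], atol=1e-12)

    def test_axes_orthonormal_random_configs(self, rng):
        for _ in range(100):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            d = rng.normal(size=3)
            d -= (d @ n) * n  # in-plane direction
            d /= np.linalg.norm(d)
            d += rng.normal(0, 0.1) * n  # small out-of-plane tilt (< 30 deg gate)
            d /= np.linalg.norm(d)
            basis = np.linalg.svd(n[None, :])[2][1:]
            pts = rng.uniform(-1, 1, (10, 2)) @ basis + n * rng.normal()
            plane = fit_plane(pts)
            seat = fit_line_3d(np.outer(np.linspace(0, 1, 5), d) + pts[0])
            fr = build_sagittal_frame(plane, seat, rng.normal(size=3))
            M = np.array([fr.x_axis, fr.y_axis, fr.z_axis])
            np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(np.cross(fr.x_axis, fr.y_axis),
                                       fr.z_axis, atol=1e-9)
            assert fr.y_axis[1] >= 0

    def test_out_of_plane_seat_line_rejected(self):
        plane = fit_plane(np.array([[0, 0, 1], [1, 0, 1], [0, 1, 1]], dtype=float))
        steep = fit_line_3d(np.array([[0, 0, 0], [0.1, 0, 1]], dtype=float))
        with pytest.raises(ConfigurationError):
            build_sagittal_frame(plane, steep, np.zeros(3))

    def test_projection_examples(self):
        plane = fit_plane(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 3, 0]],
                                   dtype=float))
        seat = fit_line_3d(np.array([[0, 0, 0], [1, 0, 0]], dtype=float))
        fr = build_sagittal_frame(plane, seat, np.zeros(3))
        np.testing.assert_allclose(project_to_frame(np.array([3.0, 4, 5]), fr),
                                   [3, 4], atol=1e-12)
        np.testing.assert_allclose(project_to_frame(np.zeros(3), fr), [0, 0])

    def test_projection_is_contraction(self, rng):
        plane = fit_plane(rng.normal(size=(10, 3)) * [1, 1, 0.01])
        seat = fit_line_3d(np.outer(np.linspace(0, 1, 4), [1, 0.2, 0]))
        fr = build_sagittal_frame(plane, seat, np.zeros(3))
        a, b = rng.normal(size=(2, 3))
        d2 = np.linalg.norm(np.subtract(*project_to_frame(np.array([a, b]), fr)))
        assert d2 <= np.linalg.norm(a - b) + 1e-12


class TestAngles:
    @pytest.mark.parametrize("e_ref,e_tgt,expected", [
        ((1, 0), (0, 1), 90.0),
        ((1, 0), (1, 0), 0.0),
        ((1, 0), (np.sqrt(2) / 2, -np.sqrt(2) / 2), -45.0),
        ((0, 1), (1, 0), -90.0),
        ((1, 0), (-1, 0), 180.0),
    ])
    def test_signed_angle_examples(self, e_ref, e_tgt, expected):
        assert signed_angle(e_ref, e_tgt) == pytest.approx(expected, abs=1e-12)

    def test_signed_angle_antisymmetry(self, rng):
        for _ in range(200):
            a, b = rng.normal(size=(2, 2))
            ang = signed_angle(a, b)
            if abs(ang) == pytest.approx(180.0):
                continue
            assert signed_angle(b, a) == pytest.approx(-ang, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(RomVisionError):
            signed_angle((0, 0), (1, 0))
        with pytest.raises(RomVisionError):
            plane_normal_angle((0, 0, 0), (0, 0, 1))

    @pytest.mark.parametrize("n_j,n_ref,expected", [
        ((0, 0, 1), (0, 0, 1), 0.0),
        ((0, 0, -1), (0, 0, 1), 0.0),
        ((0, 0.5, np.sqrt(3) / 2), (0, 0, 1), 30.0),
    ])
    def test_plane_normal_angle_examples(self, n_j, n_ref, expected):
        assert plane_normal_angle(n_j, n_ref) == pytest.approx(expected, abs=1e-9)

    def test_plane_normal_angle_symmetric(self, rng):
        a, b = rng.normal(size=(2, 3))
        assert plane_normal_angle(a, b) == pytest.approx(plane_normal_angle(b, a))

    def test_collinear_markers_give_zero_knee_angle(self):
        # calibration posture: thigh and calf strips collinear -> knee angle 0
        thigh = fit_line_2d(np.array([[0, 0], [1, 0.5], [2, 1.0]]))
        calf = fit_line_2d(np.array([[2, 1.0], [3, 1.5], [4, 2.0]]))
        assert signed_angle(thigh.direction, calf.direction) == pytest.approx(0, abs=1e-9)
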