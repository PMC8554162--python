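"""Camera model: projection round trips, distortion, depth registration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from romvision.camera import (
    Calibration,
    CameraIntrinsics,
    DistortionCoefficients,
    ExtrinsicRegistration,
    apply_distortion,
    camera_to_pixel,
    pixel_to_camera,
    register_depth_to_color,
    undistort,
)
from romvision.errors import (
    BehindCameraError,
    ConfigurationError,
    ConvergenceError,
    InvalidDepthError,
)


class TestPixelCameraTransforms:
    def test_principal_point_ray_is_optical_axis(self, simple_intrinsics):
        p = pixel_to_camera(320, 240, 2.0, simple_intrinsics)
        np.testing.assert_allclose(p, [0.0, 0.0, 2.0])

    def test_off_axis_pixel(self, simple_intrinsics):
        p = pixel_to_camera(820, 240, 2.0, simple_intrinsics)
        np.testing.assert_allclose(p, [2.0, 0.0, 2.0])

    def test_forward_projection_examples(self, simple_intrinsics):
        assert camera_to_pixel(np.array([0.0, 0.0, 1.0]), simple_intrinsics) == (320, 240)
        u, v = camera_to_pixel(np.array([1.0, 0.5, 2.0]), simple_intrinsics)
        assert (u, v) == (570.0, 365.0)

    def test_round_trip_random_pixels(self, simple_intrinsics, rng):
        u = rng.uniform(0, 640, 100)
        v = rng.uniform(0, 480, 100)
        z = rng.uniform(0.3, 5.0, 100)
        pts = pixel_to_camera(u, v, z, simple_intrinsics)
        u2, v2 = camera_to_pixel(pts, simple_intrinsics)
        np.testing.assert_allclose(u2, u, atol=1e-9)
        np.testing.assert_allclose(v2, v, atol=1e-9)

    def test_projective_invariance(self, simple_intrinsics):
        p = np.array([0.4, -0.2, 1.5])
        u1 = camera_to_pixel(p, simple_intrinsics)
        u2 = camera_to_pixel(3.7 * p, simple_intrinsics)
        np.testing.assert_allclose(u1, u2)

    def test_invalid_depth_rejected(self, simple_intrinsics):
        with pytest.raises(InvalidDepthError):
            pixel_to_camera(10, 10, 0.0, simple_intrinsics)
        with pytest.raises(InvalidDepthError):
            pixel_to_camera(10, 10, np.nan, simple_intrinsics)

    def test_behind_camera_rejected(self, simple_intrinsics):
        with pytest.raises(BehindCameraError):
            camera_to_pixel(np.array([0.0, 0.0, -1.0]), simple_intrinsics)

    @given(u=st.floats(0, 639), v=st.floats(0, 479), z=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, u, v, z):
        intr = CameraIntrinsics(fx=500.0, fy=500.0, u0=320.0, v0=240.0,
                                width=640, height=480)
        u2, v2 = camera_to_pixel(pixel_to_camera(u, v, z, intr), intr)
        assert abs(u2 - u) < 1e-9 and abs(v2 - v) < 1e-9

    def test_intrinsics_validation(self):
        with pytest.raises(ConfigurationError):
            CameraIntrinsics(fx=-1, fy=500, u0=320, v0=240, width=640, height=480)
        with pytest.raises(ConfigurationError):
            CameraIntrinsics(fx=500, fy=500, u0=700, v0=240, width=640, height=480)


class TestDistortion:
    def test_zero_coefficients_identity(self):
        d = DistortionCoefficients()
        assert apply_distortion(0.3, -0.7, d) == (0.3, -0.7)

    def test_k1_only_hand_case(self):
        d = DistortionCoefficients(k1=0.1)
        x, y = apply_distortion(0.5, 0.0, d)
        assert x == pytest.approx(0.5125, abs=1e-12)
        assert y == 0.0

    def test_origin_fixed_point(self):
        d = DistortionCoefficients(k1=0.2, k2=-0.1, k3=0.05, p1=0.01, p2=-0.02)
        assert apply_distortion(0.0, 0.0, d) == (0.0, 0.0)

    def test_undistort_hand_case(self):
        d = DistortionCoefficients(k1=0.1)
        x, y = undistort(0.5125, 0.0, d)
        assert x == pytest.approx(0.5, abs=1e-6)
        assert y == pytest.approx(0.0, abs=1e-6)

    def test_undistort_round_trip(self, rng):
        d = DistortionCoefficients(k1=0.05, p1=0.001)
        xd = rng.uniform(-0.6, 0.6, 100)
        yd = rng.uniform(-0.6, 0.6, 100)
        x, y = undistort(xd, yd, d)
        xd2, yd2 = apply_distortion(x, y, d)
        assert np.max(np.hypot(xd2 - xd, yd2 - yd)) < 1e-8

    def test_undistort_zero_is_identity(self):
        x, y = undistort(0.4, -0.3, DistortionCoefficients())
        assert (x, y) == (0.4, -0.3)

    def test_nonconvergence_reports_residual(self):
        d = DistortionCoefficients(k1=-3.0, k2=5.0)  # wildly non-invertible
        with pytest.raises(ConvergenceError) as ei:
            undistort(0.9, 0.9, d)
        assert ei.value.residual is not None and ei.value.residual > 0


def _small_calib(t=(0.0, 0.0, 0.0)) -> Calibration:
    intr = CameraIntrinsics(fx=500.0, fy=500.0, u0=320.0, v0=240.0,
                            width=640, height=480)
    return Calibration(color=intr, depth=intr,
                       extrinsic=ExtrinsicRegistration(R=np.eye(3),
                                                       t=np.asarray(t)))


class TestRegistration:
    def test_identity_registration_reproduces_input(self, rng):
        calib = _small_calib()
        depth = np.zeros((480, 640))
        vv = rng.integers(0, 480, 200)
        uu = rng.integers(0, 640, 200)
        depth[vv, uu] = rng.uniform(0.5, 3.0, 200)
        out = register_depth_to_color(depth, calib)
        np.testing.assert_allclose(out[vv, uu], depth[vv, uu])

    def test_single_pixel_translation_offset(self):
        calib = _small_calib(t=(0.05, 0.0, 0.0))
        depth = np.zeros((480, 640))
        depth[240, 320] = 1.0
        out = register_depth_to_color(depth, calib)
        # x-translation of 5 cm at 1 m -> 25-pixel shift along u
        assert out[240, 345] == pytest.approx(1.0)
        assert out[240, 320] == 0.0

    def test_z_buffer_keeps_nearer_point(self):
        # with t = (0.004, 0, 0): pixel (240, 320) at z=1 shifts by 2 px to
        # u=322; pixel (240, 321) at z=2 shifts by 1 px to u=322 -- collision
        calib = _small_calib(t=(0.004, 0.0, 0.0))
        depth = np.zeros((480, 640))
        depth[240, 320] = 1.0
        depth[240, 321] = 2.0
        out = register_depth_to_color(depth, calib)
        assert out[240, 322] == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        calib = _small_calib()
        with pytest.raises(ConfigurationError):
            register_depth_to_color(np.zeros((100, 100)), calib)

    def test_extrinsic_validation(self):
        with pytest.raises(ConfigurationError):
            ExtrinsicRegistration(R=np.eye(3) * 2.0, t=np.zeros(3))
        R_reflect = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ConfigurationError):
            ExtrinsicRegistration(R=R_reflect, t=np.zeros(3))
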