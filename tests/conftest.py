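import numpy as np
import pytest

from romvision.camera import CameraIntrinsics
from romvision.synthetic import LegSceneConfig


@pytest.fixture
def simple_intrinsics() -> CameraIntrinsics:
    """640x480 camera with fx = fy = 500 and centered principal point."""
    return CameraIntrinsics(fx=500.0, fy=500.0, u0=320.0, v0=240.0,
                            width=640, height=480)


def small_scene() -> LegSceneConfig:
    """Scene at 640x480 for fast unit tests (everything scaled with fx)."""
    intr = CameraIntrinsics(fx=300.0, fy=300.0, u0=319.5, v0=239.5,
                            width=640, height=480)
    return LegSceneConfig(color_intrinsics=intr, depth_intrinsics=intr,
                          sample_step=0.003)


@pytest.fixture
def small_scene_cfg() -> LegSceneConfig:
    return small_scene()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
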