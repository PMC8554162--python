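"""File formats: calibration YAML, PNG frame sequences, angle/ROM outputs.

Calibration files are YAML with ``color`` / ``depth`` intrinsic blocks
(fx, fy, u0, v0, width, height, distortion: [k1, k2, k3, p1, p2]) and an
``extrinsic`` block (R: 9 row-major values, t: 3 values in meters) mapping
depth-camera coordinates into color-camera coordinates.

Frame sequences live in a directory as ``frame_NNNNNN_color.png`` (8-bit
RGB) plus ``frame_NNNNNN_depth.png`` (16-bit grayscale, millimeters) or
``frame_NNNNNN_depth.npy`` (float meters); the dialect and fps are declared
in ``meta.yaml``.  Depth is always converted to float meters on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .camera import (
    Calibration,
    CameraIntrinsics,
    DistortionCoefficients,
    ExtrinsicRegistration,
    RGBDFrame,
)
from .errors import ConfigurationError
from .pipeline import JointAngleSeries, ROMResult
from .segmentation import SegmentationConfig
from .synthetic import SyntheticSession

__all__ = [
    "load_calibration",
    "save_calibration",
    "load_segmentation_config",
    "read_frames",
    "write_session",
    "write_series_csv",
    "write_rom_json",
    "read_reference_trace",
]


def _intrinsics_from_dict(d: dict) -> tuple[CameraIntrinsics, DistortionCoefficients]:
    intr = CameraIntrinsics(
        fx=float(d["fx"]), fy=float(d["fy"]), u0=float(d["u0"]),
        v0=float(d["v0"]), width=int(d["width"]), height=int(d["height"]),
    )
    dist = DistortionCoefficients(*[float(x) for x in d.get("distortion", [0] * 5)])
    return intr, dist


def load_calibration(path) -> Calibration:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        color, color_dist = _intrinsics_from_dict(doc["color"])
        depth, depth_dist = _intrinsics_from_dict(doc["depth"])
        ext = doc.get("extrinsic", {})
        R = np.asarray(ext.get("R", np.eye(3).ravel()), dtype=float).reshape(3, 3)
        t = np.asarray(ext.get("t", [0, 0, 0]), dtype=float)
    except KeyError as e:
        raise ConfigurationError(f"calibration file missing key: {e}") from e
    return Calibration(color=color, depth=depth, color_dist=color_dist,
                       depth_dist=depth_dist,
                       extrinsic=ExtrinsicRegistration(R=R, t=t))


def save_calibration(calib: Calibration, path) -> None:
    def block(intr: CameraIntrinsics, dist: DistortionCoefficients) -> dict:
        return {
            "fx": intr.fx, "fy": intr.fy, "u0": intr.u0, "v0": intr.v0,
            "width": intr.width, "height": intr.height,
            "distortion": [dist.k1, dist.k2, dist.k3, dist.p1, dist.p2],
        }

    doc = {
        "color": block(calib.color, calib.color_dist),
        "depth": block(calib.depth, calib.depth_dist),
        "extrinsic": {
            "R": [float(x) for x in calib.extrinsic.R.ravel()],
            "t": [float(x) for x in calib.extrinsic.t],
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_segmentation_config(path) -> SegmentationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kwargs = {}
    for key in ("reference_color", "threshold", "min_component_size",
                "bin_count", "role_gate"):
        if key in doc:
            kwargs[key] = doc[key]
    if "reference_color" in kwargs:
        kwargs["reference_color"] = tuple(kwargs["reference_color"])
    if "role_colors" in doc:
        kwargs["role_colors"] = {r: tuple(c) for r, c in doc["role_colors"].items()}
    return SegmentationConfig(**kwargs)


def read_frames(directory) -> Iterator[RGBDFrame]:
    """Iterate the RGB-D frames of a session directory (sorted by index)."""
    directory = Path(directory)
    meta = {}
    meta_path = directory / "meta.yaml"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    fps = float(meta.get("fps", 30.0))
    for i, color_path in enumerate(sorted(directory.glob("frame_*_color.png"))):
        stem = color_path.name[: -len("_color.png")]
        color = iio.imread(color_path)
        npy = directory / f"{stem}_depth.npy"
        png = directory / f"{stem}_depth.png"
        if npy.exists():
            depth = np.load(npy).astype(float)
        elif png.exists():
            depth = iio.imread(png).astype(float) / 1000.0  # mm -> m
        else:
            raise ConfigurationError(f"no depth image for {stem}")
        yield RGBDFrame(color=color, depth=depth, timestamp=i / fps,
                        frame_index=i)


def write_session(session: SyntheticSession, directory) -> None:
    """Write a synthetic session as PNG frames + calibration + truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame, _ in session.frames():
        stem = f"frame_{frame.frame_index:06d}"
        iio.imwrite(directory / f"{stem}_color.png", frame.color)
        depth_mm = np.round(frame.depth * 1000.0)
        depth_mm[~np.isfinite(depth_mm)] = 0
        iio.imwrite(directory / f"{stem}_depth.png",
                    np.clip(depth_mm, 0, 65535).astype(np.uint16))
    save_calibration(session.calibration(), directory / "calibration.yaml")
    session.truth.to_csv(directory / "truth.csv", index=False)
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump({
            "mode": session.mode,
            "fps": session.cfg.fps,
            "depth_dialect": "png16_mm",
            "seed": session.noise.seed,
            "role_colors": {r: list(c)
                            for r, c in session.cfg.role_colors.items()},
        }, fh, sort_keys=False)


def write_series_csv(series: JointAngleSeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def write_rom_json(rom: ROMResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(rom.to_dict(), fh, indent=2)


def read_reference_trace(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an angle-sensor trace CSV with columns time_s, angle_deg."""
    df = pd.read_csv(path)
    if not {"time_s", "angle_deg"} <= set(df.columns):
        raise ConfigurationError("reference trace needs columns time_s, angle_deg")
    return df["time_s"].to_numpy(float), df["angle_deg"].to_numpy(float)
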