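"""Colored-strip marker extraction from RGB frames.

The strips are a saturated color chosen to stand out from the scene, so
segmentation is a Euclidean distance threshold in RGB space: a pixel is
foreground iff ||(R, G, B) − (R1, G1, B1)|| <= T.  Foreground pixels are
grouped into 8-connected components, small components are discarded, and
components are tagged with an anatomical role (seat / thigh / calf) either by
per-role reference colors or by nearest-centroid tracking against the
previous frame.

Because a strip is many pixels wide but the line fit wants one depth-bearing
sample per location along the strip, each component is partitioned into bins
along its dominant image axis and the per-bin pixel with the median valid
depth is emitted — a cheap robustification against depth speckle and
registration parallax at strip edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import InsufficientDepthError, MarkerLostError

__all__ = [
    "SegmentationConfig",
    "MarkerComponent",
    "LabeledMarker",
    "ROLES",
    "color_distance_mask",
    "extract_components",
    "assign_roles",
    "sample_with_median_depth",
]

ROLES = ("seat", "thigh", "calf")


@dataclass
class SegmentationConfig:
    """Marker segmentation parameters.

    ``reference_color`` is the shared strip color; ``role_colors`` optionally
    gives one reference color per role, which bypasses centroid tracking
    (each role segmented independently).  ``threshold`` is the RGB-space
    Euclidean distance T; ``role_gate`` the maximum centroid distance
    (pixels) for tracking-based role assignment.
    """

    reference_color: tuple[int, int, int] = (40, 60, 220)
    threshold: float = 60.0
    min_component_size: int = 40
    bin_count: int = 32
    role_gate: float = 120.0
    role_colors: dict[str, tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        for c in self.reference_color:
            if not 0 <= c <= 255:
                raise ValueError("reference color channels must be in [0, 255]")


@dataclass
class MarkerComponent:
    """One connected component of marker pixels.

    ``pixels`` is an (N, 2) integer array of (u, v) coordinates; ``centroid``
    the continuous (u, v) mean.
    """

    pixels: np.ndarray
    role: str = "unassigned"

    @property
    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class LabeledMarker:
    """Role-tagged depth-bearing samples: (N, 3) array of (u, v, z)."""

    role: str
    samples: np.ndarray


def color_distance_mask(color_image: np.ndarray, cfg: SegmentationConfig,
                        reference_color=None) -> np.ndarray:
    """Binarize an RGB image by distance to a reference color.

    Returns a single-channel uint8 mask: 255 where the Euclidean RGB distance
    to the reference is <= cfg.threshold, else 0 (inclusive boundary).
    """
    ref = np.asarray(
        cfg.reference_color if reference_color is None else reference_color,
        dtype=np.int32,
    )
    img = np.asarray(color_image).astype(np.int32, copy=False)
    diff = img - ref
    # squared-distance comparison: L <= T  <=>  L^2 <= T^2 (no sqrt needed)
    dist2 = diff[..., 0] ** 2 + diff[..., 1] ** 2 + diff[..., 2] ** 2
    return np.where(dist2 <= cfg.threshold * cfg.threshold, 255, 0).astype(np.uint8)


def extract_components(mask: np.ndarray, min_size: int) -> list[MarkerComponent]:
    """8-connected components of a binary mask, size-filtered, largest first."""
    labels = measure.label(np.asarray(mask) > 0, connectivity=2)
    comps = []
    for region in measure.regionprops(labels):
        if region.num_pixels < min_size:
            continue
        rc = region.coords  # (row, col) = (v, u)
        comps.append(MarkerComponent(pixels=rc[:, ::-1].copy()))
    comps.sort(key=lambda c: c.size, reverse=True)
    return comps


def assign_roles(components: list[MarkerComponent],
                 prior: dict[str, tuple[float, float]],
                 gate: float = 120.0) -> tuple[dict[str, MarkerComponent], list[str]]:
    """Match components to roles by nearest prior centroid.

    Greedy on ascending centroid distance; each component used at most once.
    Returns (assigned role -> component, missing roles).  A role is missing
    when its best available component is farther than ``gate`` pixels.
    """
    pairs = []
    for role, cen in prior.items():
        cen = np.asarray(cen, dtype=float)
        for idx, comp in enumerate(components):
            d = float(np.linalg.norm(comp.centroid - cen))
            pairs.append((d, role, idx))
    pairs.sort(key=lambda p: p[0])
    assigned: dict[str, MarkerComponent] = {}
    used: set[int] = set()
    for d, role, idx in pairs:
        if role in assigned or idx in used or d > gate:
            continue
        comp = components[idx]
        comp.role = role
        assigned[role] = comp
        used.add(idx)
    missing = [r for r in prior if r not in assigned]
    return assigned, missing


def sample_with_median_depth(component: MarkerComponent,
                             registered_depth: np.ndarray,
                             bin_count: int = 32,
                             role: str | None = None) -> LabeledMarker:
    """Reduce a marker component to depth-robust (u, v, z) samples.

    The pixels are partitioned into ``bin_count`` bins along the component's
    dominant image-plane axis (largest-variance direction of the pixel
    coordinates); each bin contributes one representative sample at the
    centroid of its valid pixels (sub-pixel, avoiding pixel-grid aliasing)
    whose depth value is the median of the bin's valid depths (robust to
    depth speckle).  Bins without valid depth are skipped; with
    bin_count >= 2, fewer than two populated bins raises
    :class:`InsufficientDepthError` (a line cannot be fitted).
    """
    px = np.asarray(component.pixels, dtype=float)
    if len(px) == 0:
        raise InsufficientDepthError("empty marker component")
    z = registered_depth[component.pixels[:, 1], component.pixels[:, 0]]
    valid = np.isfinite(z) & (z > 0)

    centered = px - px.mean(axis=0)
    cov = centered.T @ centered
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    t = centered @ axis
    lo, hi = t.min(), t.max()
    if hi - lo <= 0:
        edges = np.array([lo - 0.5, lo + 0.5])
        bin_count = 1
    else:
        edges = np.linspace(lo, hi, bin_count + 1)
    bins = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, bin_count - 1)

    samples = []
    for b in range(bin_count):
        sel = (bins == b) & valid
        if not np.any(sel):
            continue
        idx = np.nonzero(sel)[0]
        zs = np.sort(z[idx])
        med_z = zs[(len(zs) - 1) // 2]
        cen = px[idx].mean(axis=0)
        samples.append((cen[0], cen[1], med_z))
    if len(samples) < min(bin_count, 2):
        raise InsufficientDepthError(
            f"only {len(samples)} bins with valid depth (need "
            f"{min(bin_count, 2)})"
        )
    return LabeledMarker(role=role or component.role,
                         samples=np.asarray(samples, dtype=float))


def extract_labeled_markers(color_image: np.ndarray,
                            registered_depth: np.ndarray,
                            cfg: SegmentationConfig,
                            prior: dict[str, tuple[float, float]] | None = None,
                            roles=ROLES,
                            frame_index: int | None = None
                            ) -> tuple[dict[str, LabeledMarker], list[str]]:
    """Segment, role-tag and depth-sample all markers of one frame.

    With per-role reference colors each role is segmented independently (the
    largest sufficiently big component of its color wins); otherwise a single
    shared-color mask is tracked against ``prior`` centroids.  Returns
    (role -> LabeledMarker, missing roles); depth failures mark the role
    missing rather than aborting.
    """
    comps_by_role: dict[str, MarkerComponent] = {}
    missing: list[str] = []
    if cfg.role_colors is not None:
        for role in roles:
            mask = color_distance_mask(color_image, cfg, cfg.role_colors[role])
            comps = extract_components(mask, cfg.min_component_size)
            if not comps:
                missing.append(role)
                continue
            if prior is not None and role in prior:
                cen = np.asarray(prior[role], dtype=float)
                comps.sort(key=lambda c: float(np.linalg.norm(c.centroid - cen)))
            comp = comps[0]
            comp.role = role
            comps_by_role[role] = comp
    else:
        if prior is None:
            raise MarkerLostError(
                "tracking", frame_index
            )  # shared-color segmentation needs prior centroids
        mask = color_distance_mask(color_image, cfg)
        comps = extract_components(mask, cfg.min_component_size)
        comps_by_role, missing = assign_roles(
            comps, {r: prior[r] for r in roles}, gate=cfg.role_gate
        )

    markers: dict[str, LabeledMarker] = {}
    for role, comp in comps_by_role.items():
        try:
            markers[role] = sample_with_median_depth(
                comp, registered_depth, cfg.bin_count, role=role
            )
        except InsufficientDepthError:
            missing.append(role)
    return markers, missing
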