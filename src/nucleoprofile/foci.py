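"""Marker-channel focus detection and per-nucleus focus metrics.

A focus is a connected bright component of the marker channel inside the
nucleus.  The detection threshold is the intra-nucleus background floor
(median) plus ``k`` times a robust spread (1.4826 * MAD), with a minimum
rise above the floor so that diffuse non-focal signal (e.g. a fluorescent
nucleolus interior) is not segmented as one giant focus.  Components use
8-connectivity because merged heterochromatin-associated clusters flow
into each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from skimage.morphology import remove_small_objects

from .image import NucleusImage

__all__ = [
    "Focus",
    "FociSet",
    "ClusterStats",
    "detect_foci",
    "labeling_index",
    "cluster_stats",
    "line_profile",
    "heatmap_export",
    "flame_lut",
]


@dataclass
class Focus:
    """One detected connected bright component in the marker channel."""

    label: int
    area_px: int
    mean_intensity: float
    max_intensity: float
    centroid: tuple[float, float]
    inside_nucleolus: bool
    boundary_distance_px: float  # signed distance to nucleolus boundary; negative inside


@dataclass
class FociSet:
    """Per-nucleus collection of detected foci with summary metrics."""

    foci: list[Focus]
    nucleus_area_px: int
    threshold: float
    label_image: np.ndarray = field(repr=False, default=None)

    @property
    def count(self) -> int:
        return len(self.foci)

    @property
    def labeled(self) -> bool:
        return self.count > 0

    @property
    def total_area_px(self) -> int:
        return int(sum(f.area_px for f in self.foci))

    @property
    def mean_area_px(self) -> float:
        return float(np.mean([f.area_px for f in self.foci])) if self.foci else 0.0

    @property
    def area_sd(self) -> float:
        if self.count < 2:
            return 0.0
        return float(np.std([f.area_px for f in self.foci], ddof=1))

    @property
    def mean_intensity(self) -> float:
        if not self.foci:
            return 0.0
        areas = np.array([f.area_px for f in self.foci], dtype=float)
        means = np.array([f.mean_intensity for f in self.foci])
        return float(np.sum(areas * means) / areas.sum())

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.total_area_px / self.nucleus_area_px

    def foci_mask(self) -> np.ndarray:
        return self.label_image > 0


def _signed_nucleolus_distance(nucleolus_mask: np.ndarray) -> np.ndarray:
    """Signed pixel distance to the nucleolus boundary (negative inside)."""
    outside = ndi.distance_transform_edt(~nucleolus_mask)
    inside = ndi.distance_transform_edt(nucleolus_mask)
    return outside - inside


def detect_foci(
    image: NucleusImage,
    nucleus_mask: np.ndarray,
    nucleolus_mask: np.ndarray | None = None,
    k: float = 3.0,
    min_rise: float = 40.0,
    min_focus_px: int = 3,
    threshold: float | None = None,
) -> FociSet:
    """Detect marker foci inside the segmented nucleus.

    ``threshold`` overrides the automatic rule
    ``median + max(k * 1.4826 * MAD, min_rise)``.  An empty set is a valid
    result — the nucleus is then unlabeled.
    """
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    marker = image.marker.astype(float)
    vals = marker[nucleus_mask]
    if threshold is None:
        floor = float(np.median(vals))
        mad = float(np.median(np.abs(vals - floor)))
        threshold = floor + max(k * 1.4826 * mad, min_rise)
    binary = nucleus_mask & (marker > threshold)
    binary = remove_small_objects(binary, max_size=min_focus_px - 1)
    labels = label(binary, connectivity=2)
    signed_dist = (
        _signed_nucleolus_distance(nucleolus_mask)
        if nucleolus_mask is not None and nucleolus_mask.any()
        else None
    )
    foci: list[Focus] = []
    for rp in regionprops(labels, intensity_image=marker):
        cy, cx = rp.centroid
        iy, ix = int(round(cy)), int(round(cx))
        inside = bool(nucleolus_mask[iy, ix]) if signed_dist is not None else False
        dist = float(signed_dist[iy, ix]) if signed_dist is not None else float("nan")
        foci.append(
            Focus(
                label=int(rp.label),
                area_px=int(rp.area),
                mean_intensity=float(rp.intensity_mean),
                max_intensity=float(rp.intensity_max),
                centroid=(float(cy), float(cx)),
                inside_nucleolus=inside,
                boundary_distance_px=dist,
            )
        )
    return FociSet(
        foci=foci,
        nucleus_area_px=int(nucleus_mask.sum()),
        threshold=float(threshold),
        label_image=labels,
    )


def labeling_index(focisets: list[FociSet]) -> float:
    """Percentage of nuclei showing any detectable focus."""
    if not focisets:
        raise ValueError("labeling index undefined for an empty population")
    return 100.0 * sum(fs.labeled for fs in focisets) / len(focisets)


@dataclass(frozen=True)
class ClusterStats:
    """Large-cluster summary for one nucleus."""

    large_count: int
    large_area_fraction: float
    size_threshold_px: float


def cluster_stats(
    fociset: FociSet,
    cluster_factor: float = 5.0,
    fallback_abs_px: float = 50.0,
    population_median_area: float | None = None,
) -> ClusterStats:
    """Count merged clusters: foci at least ``cluster_factor`` times the
    median singleton area.

    The reference singleton area is the population median when supplied.
    Without it the nucleus's own lower-quartile focus area stands in:
    within one nucleus merged clusters can make up half the components,
    which would inflate a plain median, while the smallest quartile stays
    representative of singletons.  A single-component nucleus falls back
    to the absolute threshold.
    """
    if fociset.count == 0:
        return ClusterStats(0, 0.0, float("nan"))
    areas = np.array([f.area_px for f in fociset.foci], dtype=float)
    if population_median_area is not None and population_median_area > 0:
        thr = cluster_factor * population_median_area
    elif fociset.count >= 2:
        thr = cluster_factor * float(np.quantile(areas, 0.25))
    else:
        thr = fallback_abs_px
    large = areas >= thr
    total = float(areas.sum())
    return ClusterStats(
        large_count=int(large.sum()),
        large_area_fraction=float(areas[large].sum() / total) if total > 0 else 0.0,
        size_threshold_px=float(thr),
    )


def line_profile(
    image: NucleusImage, polyline: list[tuple[float, float]]
) -> np.ndarray:
    """Marker intensities sampled at unit spacing along a polyline.

    Nearest-pixel sampling; an out-of-bounds vertex raises ``ValueError``.
    """
    if not polyline:
        raise ValueError("polyline must contain at least one vertex")
    h, w = image.shape
    for r, c in polyline:
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(f"polyline vertex ({r}, {c}) outside image bounds")
    pts: list[tuple[float, float]] = [tuple(map(float, polyline[0]))]
    for (r0, c0), (r1, c1) in zip(polyline[:-1], polyline[1:]):
        seg_len = float(np.hypot(r1 - r0, c1 - c0))
        n_steps = max(1, int(round(seg_len)))
        for i in range(1, n_steps + 1):
            t = i / n_steps
            pts.append((r0 + t * (r1 - r0), c0 + t * (c1 - c0)))
    rows = np.clip(np.rint([p[0] for p in pts]).astype(int), 0, h - 1)
    cols = np.clip(np.rint([p[1] for p in pts]).astype(int), 0, w - 1)
    return image.marker[rows, cols].astype(float)


# Flame gradient control points: black through blue, purple, red, orange,
# yellow to white, with strictly non-decreasing luminance.
_FLAME_STOPS = np.array(
    [
        (0.00, 0.00, 0.00, 0.00),
        (0.15, 0.00, 0.00, 0.55),
        (0.30, 0.45, 0.00, 0.60),
        (0.50, 0.85, 0.10, 0.10),
        (0.70, 1.00, 0.55, 0.00),
        (0.88, 1.00, 1.00, 0.25),
        (1.00, 1.00, 1.00, 1.00),
    ]
)


def flame_lut() -> np.ndarray:
    """(256, 3) uint8 lookup table for the flame-like gradient."""
    x = np.linspace(0.0, 1.0, 256)
    lut = np.stack(
        [np.interp(x, _FLAME_STOPS[:, 0], _FLAME_STOPS[:, i + 1]) for i in range(3)],
        axis=1,
    )
    return np.clip(np.rint(lut * 255), 0, 255).astype(np.uint8)


def heatmap_export(
    image: NucleusImage, nucleus_mask: np.ndarray, path: str | Path
) -> Path:
    """Write a false-color PNG of marker intensities inside the nucleus.

    Pure visualization: masked-out pixels are black, and the color map is
    luminance-monotone so brighter always reads as more active.
    """
    lut = flame_lut()
    rgb = lut[image.marker]
    rgb[~np.asarray(nucleus_mask, bool)] = 0
    path = Path(path)
    iio.imwrite(path, rgb)
    return path
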