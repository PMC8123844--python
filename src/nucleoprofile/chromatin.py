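"""Chromatin-channel segmentation and area metrics.

Chromatin density is read directly from pixel lightness on the 8-bit scale
(0 = no chromatin, 255 = highly condensed).  The nucleus is the largest
bright connected component, the nucleolus the largest dark region inside
it, and heterochromatin the bright intra-nucleus pixel class found by an
inter-class-variance (Otsu) split of the intra-nucleus histogram.  All
areas are pixel counts; the heterochromatin percentage is
``100 * hc_area / nucleus_area``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import (
    dilation,
    disk,
    erosion,
    opening,
    remove_small_objects,
)

from .image import NucleusImage

__all__ = [
    "ChromatinMetrics",
    "SegmentationError",
    "segment_nucleus",
    "segment_nucleolus",
    "threshold_heterochromatin",
    "chromatin_metrics",
    "measure_chromatin",
]


class SegmentationError(ValueError):
    """Raised when no nucleus can be found in an image."""


@dataclass(frozen=True)
class ChromatinMetrics:
    """Pixel-count area metrics for one nucleus."""

    nucleus_area_px: int
    nucleolus_area_px: int
    hc_area_px: int
    hc_percent: float

    def __post_init__(self) -> None:
        if self.hc_area_px > self.nucleus_area_px:
            raise ValueError("heterochromatin area exceeds nucleus area")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def segment_nucleus(image: NucleusImage, min_area_px: int = 500) -> np.ndarray:
    """Segment the nucleus from the chromatin channel.

    Global Otsu thresholding, hole filling, then the largest connected
    component; anything smaller than ``min_area_px`` counts as no nucleus.
    """
    chrom = image.chromatin
    if chrom.max() == chrom.min():
        raise SegmentationError("no nucleus found: constant chromatin channel")
    thr = threshold_otsu(chrom)
    fg = ndi.binary_fill_holes(chrom > thr)
    nucleus = _largest_component(fg)
    if nucleus.sum() < min_area_px:
        raise SegmentationError(
            f"no nucleus found: largest component {int(nucleus.sum())} px < {min_area_px} px"
        )
    return nucleus


def segment_nucleolus(
    image: NucleusImage,
    nucleus_mask: np.ndarray,
    percentile: float = 20.0,
    min_area_px: int = 50,
    border_erosion_px: int = 3,
) -> np.ndarray:
    """Segment the DAPI-dark nucleolus inside the nucleus.

    Candidate pixels fall strictly below the given percentile of
    intra-nucleus intensities within the eroded nucleus; the largest
    hole-filled component survives if it reaches ``min_area_px``.  An empty
    mask is a valid result (no resolvable nucleolus).
    """
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    inner = erosion(nucleus_mask, disk(border_erosion_px))
    if not inner.any():
        return np.zeros_like(nucleus_mask, dtype=bool)
    chrom = image.chromatin.astype(float)
    thr = np.percentile(chrom[inner], percentile)
    cand = inner & (chrom < thr)
    cand = opening(cand, disk(1))
    nucleolus = _largest_component(cand)
    if nucleolus.sum() < min_area_px:
        return np.zeros_like(nucleus_mask, dtype=bool)
    return ndi.binary_fill_holes(nucleolus) & nucleus_mask


def threshold_heterochromatin(
    image: NucleusImage,
    nucleus_mask: np.ndarray,
    nucleolus_mask: np.ndarray | None = None,
    fixed_threshold: float | None = None,
    min_speckle_px: int = 4,
    min_contrast: float = 30.0,
) -> np.ndarray:
    """Threshold bright heterochromatin inside the nucleus.

    The default threshold is the Otsu inter-class-variance split of
    intra-nucleus intensities (excluding the dark nucleolus when its mask
    is supplied, so the bimodal split separates heterochromatin from
    nucleoplasm rather than nucleolus from everything else).  A fixed user
    threshold can replace the automatic one for parity with manual
    workflows.  When the two intensity classes differ by less than
    ``min_contrast`` the histogram is treated as unimodal and the mask is
    empty; a degenerate constant histogram also yields an empty mask, with
    a warning.  Speckles below ``min_speckle_px`` are removed.
    """
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    domain = nucleus_mask
    if nucleolus_mask is not None and nucleolus_mask.any():
        # dilate the exclusion so dark nucleolus-boundary pixels (where the
        # segmented nucleolus runs a little small) cannot skew the split
        domain = nucleus_mask & ~dilation(nucleolus_mask, disk(2))
    chrom = image.chromatin.astype(float)
    vals = chrom[domain]
    if vals.max() == vals.min():
        warnings.warn(
            "degenerate intra-nucleus intensity histogram; empty heterochromatin mask",
            stacklevel=2,
        )
        return np.zeros_like(nucleus_mask, dtype=bool)
    if fixed_threshold is not None:
        thr = float(fixed_threshold)
    else:
        thr = float(threshold_otsu(vals))
        if (vals >= thr).mean() > 0.6:
            # the split isolated a dark minority (residual nucleolus), not
            # the bright heterochromatin class; re-split the upper class
            upper = vals[vals >= thr]
            if upper.max() == upper.min():
                return np.zeros_like(nucleus_mask, dtype=bool)
            thr = float(threshold_otsu(upper))
            vals = upper
        hi, lo = vals[vals >= thr], vals[vals < thr]
        if hi.size == 0 or lo.size == 0 or (hi.mean() - lo.mean()) < min_contrast:
            return np.zeros_like(nucleus_mask, dtype=bool)
    hc = domain & (chrom >= thr)
    return remove_small_objects(hc, max_size=min_speckle_px - 1)


def chromatin_metrics(
    nucleus_mask: np.ndarray,
    nucleolus_mask: np.ndarray,
    hc_mask: np.ndarray,
) -> ChromatinMetrics:
    """Area metrics (pixel counts and heterochromatin percentage)."""
    if not (nucleus_mask.shape == nucleolus_mask.shape == hc_mask.shape):
        raise ValueError("mask shapes differ")
    nucleus_area = int(nucleus_mask.sum())
    if nucleus_area == 0:
        raise ValueError("zero nucleus area")
    hc_area = int(hc_mask.sum())
    return ChromatinMetrics(
        nucleus_area_px=nucleus_area,
        nucleolus_area_px=int(nucleolus_mask.sum()),
        hc_area_px=hc_area,
        hc_percent=100.0 * hc_area / nucleus_area,
    )


def measure_chromatin(
    image: NucleusImage,
    min_nucleus_px: int = 500,
    nucleolus_percentile: float = 20.0,
    min_nucleolus_px: int = 50,
    hc_fixed_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ChromatinMetrics]:
    """Convenience pipeline: nucleus, nucleolus, heterochromatin, metrics."""
    nucleus = segment_nucleus(image, min_area_px=min_nucleus_px)
    nucleolus = segment_nucleolus(
        image, nucleus, percentile=nucleolus_percentile, min_area_px=min_nucleolus_px
    )
    hc = threshold_heterochromatin(
        image, nucleus, nucleolus_mask=nucleolus, fixed_threshold=hc_fixed_threshold
    )
    return nucleus, nucleolus, hc, chromatin_metrics(nucleus, nucleolus, hc)
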