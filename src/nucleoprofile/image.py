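"""Two-channel nucleus image container and TIFF/PNG I/O.

A nucleus image pairs a chromatin (DAPI-like) channel with a marker
(immunofluorescence) channel on the same 8-bit pixel grid.  On disk the
canonical format is a two-page grayscale TIFF: page 1 chromatin, page 2
marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


@dataclass
class NucleusImage:
    """Registered chromatin and marker channels for one nucleus.

    Parameters
    ----------
    chromatin, marker : ndarray of uint8
        Same-shape 2-D intensity grids; 0 means no signal, 255 saturated.
    pixel_size_um : float, optional
        Physical pixel pitch; metadata only, all computation is in pixels.
    """

    chromatin: np.ndarray
    marker: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.chromatin = np.asarray(self.chromatin)
        self.marker = np.asarray(self.marker)
        if self.chromatin.ndim != 2:
            raise ValueError("chromatin channel must be 2-D")
        if self.chromatin.shape != self.marker.shape:
            raise ValueError(
                f"channel shapes differ: {self.chromatin.shape} vs {self.marker.shape}"
            )
        for name, ch in (("chromatin", self.chromatin), ("marker", self.marker)):
            if ch.dtype != np.uint8:
                if ch.min() < 0 or ch.max() > 255:
                    raise ValueError(f"{name} intensities outside [0, 255]")
                object.__setattr__(self, name, ch.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.chromatin.shape


def save_nucleus_tiff(image: NucleusImage, path: str | Path) -> Path:
    """Write a two-page grayscale TIFF (page 1 chromatin, page 2 marker)."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([image.chromatin, image.marker]))
    return path


def load_nucleus_tiff(path: str | Path, pixel_size_um: float | None = None) -> NucleusImage:
    """Read a two-page grayscale TIFF written by :func:`save_nucleus_tiff`."""
    pages = tifffile.imread(Path(path))
    if pages.ndim != 3 or pages.shape[0] < 2:
        raise ValueError(f"{path}: expected a 2-page grayscale TIFF, got shape {pages.shape}")
    return NucleusImage(pages[0], pages[1], pixel_size_um=pixel_size_um)


def load_nucleus_pngs(
    chromatin_path: str | Path, marker_path: str | Path, pixel_size_um: float | None = None
) -> NucleusImage:
    """Read the two channels from separate grayscale PNG files."""
    chrom = iio.imread(Path(chromatin_path))
    marker = iio.imread(Path(marker_path))
    if chrom.ndim == 3:
        chrom = chrom[..., 0]
    if marker.ndim == 3:
        marker = marker[..., 0]
    return NucleusImage(chrom, marker, pixel_size_um=pixel_size_um)


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit PNG (255 = inside)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def load_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
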