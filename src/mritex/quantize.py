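"""Gray-level quantization of a masked region of interest.

Texture matrices are built over a discrete alphabet of L gray levels.
Continuous in-mask intensities are binned uniformly between their min
and max into levels 1..L (1-based, matching the matrix row/column
indexing convention), with half-open bins [lo, lo+w) and the top bin
closed.  A constant region maps every pixel to bin 1.  Because binning
is min-max relative, the quantized ROI — and every texture feature
derived from it — is invariant to affine rescaling of the raw
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, ShapeMismatchError

__all__ = ["QuantizedROI", "quantize"]


@dataclass(frozen=True)
class QuantizedROI:
    """A masked image region with gray levels quantized to 1..levels.

    Attributes
    ----------
    levels : int
        Gray-level quantization level L (>= 2).
    grid : ndarray of int
        Full-frame array of quantized values; 0 outside the mask,
        1..levels inside.
    mask : ndarray of bool
        ROI membership (nonzero = inside).
    raw_values : ndarray of float
        Original intensities of the in-mask pixels, mask order
        (row-major).
    """

    levels: int
    grid: np.ndarray
    mask: np.ndarray
    raw_values: np.ndarray

    @property
    def m(self) -> int:
        """Number of pixels in the region of interest."""
        return int(self.raw_values.size)

    @property
    def pixels(self) -> np.ndarray:
        """Quantized values of the in-mask pixels (1..levels), mask order."""
        return self.grid[self.mask]

    def histogram(self) -> np.ndarray:
        """Counts per gray level, length ``levels``; sums to ``m``."""
        return np.bincount(self.pixels, minlength=self.levels + 1)[1:]


def quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> QuantizedROI:
    """Quantize in-mask intensities to gray levels 1..levels.

    Uniform min-max binning: bin width w = (max - min)/levels, value v
    falls in bin floor((v - min)/w) + 1, clipped so the maximum lands in
    the top bin.  Degenerate (constant) regions map to bin 1.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ShapeMismatchError(f"image {image.shape} vs mask {mask.shape}")
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    if not mask.any():
        raise EmptyMaskError("mask selects no pixels")

    raw = image[mask]
    lo, hi = raw.min(), raw.max()
    grid = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        grid[mask] = 1
    else:
        width = (hi - lo) / levels
        bins = np.floor((image[mask] - lo) / width).astype(np.int64) + 1
        grid[mask] = np.clip(bins, 1, levels)
    return QuantizedROI(levels=int(levels), grid=grid, mask=mask, raw_values=raw)
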