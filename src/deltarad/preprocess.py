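"""ROI intensity normalization and gray-level quantization.

MR intensities are arbitrary-unit, so before texture matrices are built the
in-mask dynamic range is limited to mean +/- 3 sigma (outliers clipped, ROI
geometry untouched) and the result is quantized to ``G`` integer gray
levels (default 64) by histogram equalization: a voxel of intensity ``x``
receives level ``ceil(G * F(x))`` where ``F`` is the empirical CDF over
in-mask voxels. Level occupancies come out as equal as ties permit, which
makes the downstream texture features insensitive to monotone intensity
rescaling. All statistics (mean, SD, CDF) are ROI statistics — voxels
outside the mask never contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_N_LEVELS = 64
DEFAULT_K_SIGMA = 3.0

#: Native grid of the 0.35 T setup images, mm.
DEFAULT_VOXEL_SIZE = (1.5, 1.5, 3.0)


@dataclass
class MaskedROI:
    """A 3D image restricted to a binary mask (the contoured GTV)."""

    image: np.ndarray
    mask: np.ndarray
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.ndim != 3 or self.mask.ndim != 3:
            raise ValueError("image and mask must be 3D")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} grids differ"
            )
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.isfinite(self.image[self.mask]).all():
            raise ValueError("non-finite intensities inside the mask")

    @property
    def intensities(self) -> np.ndarray:
        """In-mask voxel values, flattened."""
        return self.image[self.mask]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class QuantizedROI:
    """Integer gray-level grid over a mask.

    ``levels`` holds values 1..n_levels inside the mask and 0 (the excluded
    sentinel) outside; every texture matrix ignores the zeros.
    """

    levels: np.ndarray
    n_levels: int
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inside = self.levels[self.levels > 0]
        if inside.size == 0:
            raise ValueError("quantized ROI is empty")
        if inside.max() > self.n_levels:
            raise ValueError("level above n_levels")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def voxel_count(self) -> int:
        return int((self.levels > 0).sum())


def limit_dynamic_range(roi: MaskedROI, k_sigma: float = DEFAULT_K_SIGMA) -> MaskedROI:
    """Clip in-mask intensities to ``[mu - k*sigma, mu + k*sigma]``.

    ``mu`` and ``sigma`` (sample SD, ``ddof=1``) are computed over in-mask
    voxels. A constant ROI (``sigma == 0``) is returned unchanged. Clipping
    rather than excluding keeps the voxel lattice intact for the texture
    matrices.
    """
    values = roi.intensities
    if values.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma == 0.0:
        log.warning("constant ROI: dynamic-range limiting is a no-op")
        return MaskedROI(roi.image.copy(), roi.mask, roi.voxel_size)
    lo, hi = mu - k_sigma * sigma, mu + k_sigma * sigma
    image = roi.image.copy()
    image[roi.mask] = np.clip(values, lo, hi)
    return MaskedROI(image, roi.mask, roi.voxel_size)


def quantize_histogram_equalization(
    roi: MaskedROI, n_levels: int = DEFAULT_N_LEVELS
) -> QuantizedROI:
    """Histogram-equalize in-mask intensities onto levels ``1..n_levels``.

    Level of voxel ``x`` is ``ceil(n_levels * F(x))`` clamped to
    ``[1, n_levels]``, with ``F`` the empirical CDF (fraction of in-mask
    voxels ``<= x``). Monotone in ``x``; tied intensities share a level.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    values = roi.intensities
    n = values.size
    # empirical CDF via ranks; ties all take the shared (max-rank) CDF value
    order = np.sort(values)
    cdf = np.searchsorted(order, values, side="right") / n
    lv = np.ceil(n_levels * cdf).astype(np.int64)
    np.clip(lv, 1, n_levels, out=lv)
    levels = np.zeros(roi.image.shape, dtype=np.int64)
    levels[roi.mask] = lv
    return QuantizedROI(levels, n_levels, roi.voxel_size)


def preprocess_roi(
    image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    k_sigma: float = DEFAULT_K_SIGMA,
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> QuantizedROI:
    """Full normalization chain: mask -> +/-k sigma clip -> equalized levels."""
    roi = MaskedROI(image, mask, voxel_size)
    return quantize_histogram_equalization(limit_dynamic_range(roi, k_sigma), n_levels)
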