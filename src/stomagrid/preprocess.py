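"""Preprocessing: maximum projection, CLAHE and median filtering.

The detection stage expects images in which local contrast between the dark
stomatal ellipses and the fluorescing mesophyll has been equalised across
the leaf (illumination and leaf-quality gradients are large at these image
sizes), then smoothed so that the threshold histograms are cleanly bimodal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

from ._fastmedian import disk_offsets, median_disk
from .image import Image2D

DEFAULT_MEDIAN_SIZE = 8
"""Median filter size: radius, in pixels, of the circular neighbourhood."""


@dataclass
class ClaheParams:
    """Contrast-limited adaptive histogram equalization parameters.

    ``slope`` is the maximum admissible slope of the per-tile intensity
    transfer function (the histogram clip level expressed as a multiple of
    the uniform bin height). ``slope_min``/``slope_max`` bound the values
    considered reasonable for this kind of image; the default working slope
    is their midpoint.
    """

    block_size: int = 127
    histogram_bins: int = 256
    slope_min: float = 8.0
    slope_max: float = 14.0
    slope: float = 11.0

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if not (self.slope_min <= self.slope <= self.slope_max):
            raise ValueError(
                f"slope {self.slope} outside [{self.slope_min}, {self.slope_max}]"
            )

    @property
    def clip_limit(self) -> float:
        """skimage clip limit equivalent to this slope.

        skimage clips each tile histogram at ``clip_limit * tile_pixels``;
        a transfer-function slope of ``s`` corresponds to clipping at
        ``s * tile_pixels / bins``, i.e. ``clip_limit = s / bins``.
        """
        return self.slope / self.histogram_bins


def max_project(stack: list[Image2D]) -> Image2D:
    """Per-pixel maximum across the planes of a z-stack."""
    if not stack:
        raise ValueError("empty stack")
    first = stack[0]
    for plane in stack[1:]:
        if plane.shape != first.shape:
            raise ValueError(f"plane shape {plane.shape} != {first.shape}")
        if plane.pixel_size_um != first.pixel_size_um:
            raise ValueError("planes have different pixel calibrations")
    proj = np.maximum.reduce([p.pixels for p in stack])
    return Image2D(proj, first.pixel_size_um, first.bit_depth)


def clahe(image: Image2D, params: ClaheParams | None = None) -> Image2D:
    """Tile-interpolated CLAHE; output spans the image's native range.

    Uses the fast variant: the transfer function is evaluated per block and
    bilinearly interpolated in-between. Internally float; re-quantised to
    the input bit depth so downstream histogram thresholds see the native
    intensity range. A perfectly flat image is returned unchanged (there is
    no contrast to stretch, and equalization of a single-bin histogram is
    degenerate).
    """
    params = params or ClaheParams()
    h, w = image.shape
    if params.block_size > h or params.block_size > w:
        raise ValueError(
            f"block_size {params.block_size} exceeds image dimensions {image.shape}"
        )
    arr = image.to_float()
    if np.ptp(arr) == 0:
        return Image2D(image.pixels.copy(), image.pixel_size_um, image.bit_depth)
    eq = exposure.equalize_adapthist(
        arr,
        kernel_size=params.block_size,
        clip_limit=params.clip_limit,
        nbins=params.histogram_bins,
    )
    return image.quantize(eq)


def median_filter(image: Image2D, size: int = DEFAULT_MEDIAN_SIZE) -> Image2D:
    """Median over a circular neighbourhood of radius ``size`` pixels.

    Edge pixels are handled by replication. Integer images go through the
    exact histogram-based kernel; float images fall back to scipy.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if np.issubdtype(image.pixels.dtype, np.integer):
        out = median_disk(image.pixels, size)
    else:
        from scipy import ndimage as ndi

        dy = np.arange(-size, size + 1)
        fp = dy[:, None] ** 2 + dy[None, :] ** 2 <= size * size
        out = ndi.median_filter(image.pixels, footprint=fp, mode="nearest")
    return Image2D(out, image.pixel_size_um, image.bit_depth)


def preprocess(
    image: Image2D,
    clahe_params: ClaheParams | None = None,
    median_size: int = DEFAULT_MEDIAN_SIZE,
) -> Image2D:
    """CLAHE followed by the median filter (the standard chain)."""
    return median_filter(clahe(image, clahe_params), median_size)
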