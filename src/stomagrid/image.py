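"""Calibrated single-channel image container and TIFF/PNG I/O.

All detection operates on :class:`Image2D`: a rectangular intensity raster
with a physical pixel calibration in micrometres per pixel side. Coordinates
are 0-based with the origin at the top-left corner; ``x`` is the column axis,
``y`` the row axis, and physical positions are ``pixel_index * pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_PIXEL_SIZE_UM = 1.11
"""Default calibration: 1.11 um per pixel side."""


@dataclass
class Image2D:
    """A calibrated 2-D grayscale image.

    Parameters
    ----------
    pixels : numpy.ndarray
        2-D array of intensities. Integer arrays must fit the declared
        ``bit_depth``; float arrays are treated as normalised to ``[0, 1]``.
    pixel_size_um : float
        Physical side length of one pixel in micrometres.
    bit_depth : int
        8 or 16. Governs the integer intensity range ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if np.issubdtype(self.pixels.dtype, np.integer):
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > self.max_value:
                raise ValueError(
                    f"integer intensities [{lo}, {hi}] exceed the "
                    f"{self.bit_depth}-bit range [0, {self.max_value}]"
                )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height_um(self) -> float:
        return self.shape[0] * self.pixel_size_um

    @property
    def width_um(self) -> float:
        return self.shape[1] * self.pixel_size_um

    @property
    def area_um2(self) -> float:
        return self.pixels.size * self.pixel_size_um**2

    def to_float(self) -> np.ndarray:
        """Return intensities normalised to ``[0, 1]`` as float64."""
        if np.issubdtype(self.pixels.dtype, np.integer):
            return self.pixels.astype(np.float64) / self.max_value
        return np.clip(self.pixels.astype(np.float64), 0.0, 1.0)

    def quantize(self, values: np.ndarray) -> "Image2D":
        """Re-quantise normalised float values to this image's bit depth."""
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        arr = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
        out = np.rint(arr * self.max_value).astype(dtype)
        return Image2D(out, self.pixel_size_um, self.bit_depth)


def read_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> Image2D:
    """Read a single-channel TIFF or PNG as an :class:`Image2D`.

    Multi-plane TIFFs are returned as a stack via :func:`read_stack` instead.
    """
    path = Path(path)
    arr = _read_array(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-plane grayscale image (shape {arr.shape})")
    return Image2D(arr, pixel_size_um, 8 if arr.dtype == np.uint8 else 16)


def read_stack(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> list[Image2D]:
    """Read a (possibly multi-plane) TIFF as a list of planes."""
    arr = _read_array(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    depth = 8 if arr.dtype == np.uint8 else 16
    return [Image2D(p, pixel_size_um, depth) for p in arr]


def _read_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_image(image: Image2D, path: str | Path) -> None:
    """Write to 16-bit (or 8-bit) grayscale TIFF or PNG, by extension."""
    path = Path(path)
    arr = image.pixels
    if not np.issubdtype(arr.dtype, np.integer):
        arr = image.quantize(arr).pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
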