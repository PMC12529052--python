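"""Seeded synthetic chlorophyll-autofluorescence leaf images with ground truth.

Grass leaves image as a bright mesophyll background (chlorophyll fluoresces)
with stomata appearing as dark ellipses arranged in parallel longitudinal
files, interleaved with dark vein stripes running along the leaf axis and a
dark border frame at the leaf edge. The generator emulates exactly those
features so that every downstream stage (preprocessing, detection, exclusion
masking, gridding, spatial statistics) can be tested against a known truth:

* stomata are placed per file by a stationary renewal process whose local
  rate follows a linear base-to-tip density gradient, with a hard-core
  minimum centre spacing so neighbouring stomata never merge;
* veins and the leaf border are rendered at the same low intensity as
  stomata, so exclusion masking is genuinely exercised;
* multiplicative Gaussian speckle plus a small blur mimics mesophyll texture.

The leaf axis is ``x`` (columns): base at ``x = 0``, tip at ``x = width``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as _draw_ellipse

from .image import DEFAULT_PIXEL_SIZE_UM, Image2D

#: Particle-area window (um^2) inside which the detector's gates accept a stoma.
DETECTABLE_AREA_UM2 = (800.0, 4000.0)

_NOISE_STREAM = 1 << 20  # sub-seed reserved for the speckle field


@dataclass
class SyntheticLeafSpec:
    """Parameters of one synthetic leaf image.

    Defaults describe a wild-type-like barley leaf segment: stomatal files
    every 100 um, stomata of 60 x 25 um (area ~1178 um^2, Crofton circularity
    ~0.76), densities rising from 60 mm^-2 at the base to 90 mm^-2 at the tip
    (tip:base ~ 1.5), three longitudinal veins of 150 um width and a 150 um
    dark border frame.
    """

    width_mm: float = 4.0
    height_mm: float = 4.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    base_density_mm2: float = 60.0
    tip_density_mm2: float = 90.0
    file_spacing_um: float = 100.0
    stoma_major_um: float = 60.0
    stoma_minor_um: float = 25.0
    stoma_intensity_frac: float = 0.25
    vein_count: int = 3
    vein_width_um: float = 150.0
    noise_sd_frac: float = 0.15
    seed: int = 0
    # rendering / layout details
    border_um: float = 150.0
    clearance_um: float = 25.0
    background_mean_frac: float = 0.45
    blur_sigma_px: float = 1.5
    bit_depth: int = 16

    @property
    def width_um(self) -> float:
        return self.width_mm * 1000.0

    @property
    def height_um(self) -> float:
        return self.height_mm * 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (rows, cols) = ceil(extent / pixel size)."""
        return (
            math.ceil(self.height_um / self.pixel_size_um),
            math.ceil(self.width_um / self.pixel_size_um),
        )

    @property
    def stoma_area_um2(self) -> float:
        return math.pi * (self.stoma_major_um / 2) * (self.stoma_minor_um / 2)

    @property
    def hardcore_um(self) -> float:
        """Minimum centre-to-centre distance along a file."""
        return self.stoma_major_um + self.clearance_um

    def validate(self, detectable: bool = True) -> None:
        if min(self.width_mm, self.height_mm, self.pixel_size_um) <= 0:
            raise ValueError("width_mm, height_mm and pixel_size_um must be positive")
        if not (0.0 <= self.stoma_intensity_frac < 1.0):
            raise ValueError("stoma_intensity_frac must lie in [0, 1)")
        if min(self.base_density_mm2, self.tip_density_mm2) < 0:
            raise ValueError("densities must be non-negative")
        if self.stoma_major_um >= self.width_um or self.stoma_minor_um >= self.height_um:
            raise ValueError("stoma larger than the image")
        if self.file_spacing_um < self.stoma_minor_um:
            raise ValueError(
                f"file_spacing_um ({self.file_spacing_um}) smaller than "
                f"stoma_minor_um ({self.stoma_minor_um}): files would overlap"
            )
        dmax = max(self.base_density_mm2, self.tip_density_mm2)
        if dmax > 0 and min(self.base_density_mm2, self.tip_density_mm2) == 0:
            raise ValueError(
                "a gradient touching zero density is not supported: the "
                "renewal placement rate must stay positive (use a small "
                "positive density, or zero at both ends)"
            )
        if dmax > 0:
            mean_gap = 1.0 / (dmax * self.file_spacing_um * 1e-6)
            if mean_gap <= self.hardcore_um:
                raise ValueError(
                    f"density {dmax} mm^-2 infeasible: mean along-file spacing "
                    f"{mean_gap:.1f} um does not exceed the hard-core distance "
                    f"{self.hardcore_um:.1f} um"
                )
        if detectable:
            lo, hi = DETECTABLE_AREA_UM2
            if not (lo <= self.stoma_area_um2 <= hi):
                raise ValueError(
                    f"stoma area {self.stoma_area_um2:.0f} um^2 outside the "
                    f"detectable range [{lo:.0f}, {hi:.0f}] um^2"
                )


@dataclass
class GroundTruth:
    """Rendered stomata and excluded regions of one synthetic leaf.

    ``records`` has one row per rendered stoma with columns
    ``centroid_x_um, centroid_y_um, area_um2, row_index``; ``exclusion`` is a
    boolean raster (True = vein or border, cannot harbour stomata).
    """

    records: pd.DataFrame
    exclusion: np.ndarray

    def __len__(self) -> int:
        return len(self.records)

    @property
    def centroids_um(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in micrometres."""
        return self.records[["centroid_x_um", "centroid_y_um"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def write_exclusion_png(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), (self.exclusion.astype(np.uint8)) * 255)


def _vein_bands(spec: SyntheticLeafSpec) -> list[tuple[float, float]]:
    """(y0, y1) extents in um of each vein stripe, evenly spaced."""
    bands = []
    for k in range(spec.vein_count):
        yc = (k + 0.5) / spec.vein_count * spec.height_um
        bands.append((yc - spec.vein_width_um / 2, yc + spec.vein_width_um / 2))
    return bands


def exclusion_raster(spec: SyntheticLeafSpec) -> np.ndarray:
    """Boolean raster of vein and border pixels (True = excluded)."""
    H, W = spec.shape
    px = spec.pixel_size_um
    excl = np.zeros((H, W), bool)
    b = int(round(spec.border_um / px))
    if b > 0:
        excl[:b, :] = excl[-b:, :] = True
        excl[:, :b] = excl[:, -b:] = True
    for y0, y1 in _vein_bands(spec):
        excl[int(round(y0 / px)) : int(round(y1 / px)), :] = True
    return excl


def _plantable_rows(spec: SyntheticLeafSpec) -> list[tuple[int, float]]:
    """(row_index, y_um) of stomatal files clear of veins and border."""
    b = spec.stoma_minor_um / 2
    clear = spec.clearance_um
    bands = _vein_bands(spec)
    rows = []
    y = spec.border_um + spec.file_spacing_um / 2
    irow = 0
    while y < spec.height_um - spec.border_um - b:
        ok = y - b > spec.border_um + clear and y + b < spec.height_um - spec.border_um - clear
        for y0, y1 in bands:
            if y + b > y0 - clear and y - b < y1 + clear:
                ok = False
        if ok:
            rows.append((irow, y))
        y += spec.file_spacing_um
        irow += 1
    return rows


def _row_x_extent(spec: SyntheticLeafSpec) -> tuple[float, float]:
    a = spec.stoma_major_um / 2
    lo = spec.border_um + a + spec.clearance_um
    hi = spec.width_um - spec.border_um - a - spec.clearance_um
    return lo, hi


def _density_at(spec: SyntheticLeafSpec, x_um: float | np.ndarray) -> float | np.ndarray:
    """Linear base-to-tip density gradient, stomata per mm^2."""
    return spec.base_density_mm2 + (
        spec.tip_density_mm2 - spec.base_density_mm2
    ) * np.asarray(x_um) / spec.width_um


def _sample_row(spec: SyntheticLeafSpec, rng: np.random.Generator) -> list[float]:
    """Stationary hard-core renewal positions along one file.

    Gaps are ``hardcore + Exponential(theta(x))`` with ``theta`` chosen so the
    local mean spacing equals ``1 / (density(x) * file_spacing)``; the first
    point is drawn from the forward-recurrence distribution so edge cells are
    not under-populated.
    """
    x_lo, x_hi = _row_x_extent(spec)
    if x_hi <= x_lo:
        return []
    c = spec.hardcore_um

    def theta(x: float) -> float:
        lam = float(_density_at(spec, x)) * spec.file_spacing_um * 1e-6  # per um
        return 1.0 / lam - c

    th0 = theta(x_lo)
    if rng.random() < c / (c + th0):
        x = x_lo + rng.random() * c
    else:
        x = x_lo + c + rng.exponential(th0)
    out: list[float] = []
    while x < x_hi:
        out.append(x)
        x += c + rng.exponential(theta(min(x, x_hi)))
    return out


def generate_leaf_image(spec: SyntheticLeafSpec) -> tuple[Image2D, GroundTruth]:
    """Render one synthetic leaf and its ground truth.

    Identical spec + seed gives bit-identical output. Placement uses one
    seeded sub-stream per file row, so row order (or row-parallel evaluation)
    cannot change the result; the speckle field has its own sub-stream.
    """
    spec.validate(detectable=False)
    H, W = spec.shape
    px = spec.pixel_size_um
    a_px = spec.stoma_major_um / 2 / px
    b_px = spec.stoma_minor_um / 2 / px

    excl = exclusion_raster(spec)
    S = np.ones((H, W), np.float64)
    S[excl] = spec.stoma_intensity_frac

    recs: list[tuple[float, float, float, int]] = []
    if max(spec.base_density_mm2, spec.tip_density_mm2) > 0:
        for irow, y_um in _plantable_rows(spec):
            rng_row = np.random.default_rng([spec.seed, irow])
            for x_um in _sample_row(spec, rng_row):
                recs.append((x_um, y_um, spec.stoma_area_um2, irow))
                rr, cc = _draw_ellipse(y_um / px, x_um / px, b_px, a_px, shape=(H, W))
                S[rr, cc] = spec.stoma_intensity_frac

    rng_noise = np.random.default_rng([spec.seed, _NOISE_STREAM])
    mean = spec.background_mean_frac * ((1 << spec.bit_depth) - 1)
    img = S * mean * (1.0 + rng_noise.normal(0.0, spec.noise_sd_frac, (H, W)))
    if spec.blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma_px)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    img = np.clip(np.rint(img), 0, (1 << spec.bit_depth) - 1).astype(dtype)

    records = pd.DataFrame(
        recs, columns=["centroid_x_um", "centroid_y_um", "area_um2", "row_index"]
    )
    return (
        Image2D(img, spec.pixel_size_um, spec.bit_depth),
        GroundTruth(records, excl),
    )


def expected_density_field(spec: SyntheticLeafSpec, cell_size_mm: float = 1.0) -> np.ndarray:
    """Expected stomatal density (mm^-2 of available area) per grid cell.

    Linear interpolation of the base-to-tip gradient evaluated at the cell
    centre; cells whose pixels are entirely excluded (vein/border) are zero.
    """
    spec.validate(detectable=False)
    cell_um = cell_size_mm * 1000.0
    ny = math.ceil(spec.height_um / cell_um)
    nx = math.ceil(spec.width_um / cell_um)
    xc = (np.arange(nx) + 0.5) * cell_um
    field = np.tile(np.asarray(_density_at(spec, xc), np.float64), (ny, 1))

    excl = exclusion_raster(spec)
    px = spec.pixel_size_um
    H, W = excl.shape
    cy = np.minimum(((np.arange(H) + 0.5) * px / cell_um).astype(int), ny - 1)
    cx = np.minimum(((np.arange(W) + 0.5) * px / cell_um).astype(int), nx - 1)
    n_avail = np.zeros((ny, nx))
    np.add.at(n_avail, (cy[:, None], cx[None, :]), ~excl)
    field[n_avail == 0] = 0.0
    return field


def expected_count_field(spec: SyntheticLeafSpec, cell_size_mm: float = 1.0) -> np.ndarray:
    """Analytic expectation of rendered stomata per grid cell.

    Sums, over every plantable file row, the integral of the local placement
    rate ``density(x) * file_spacing`` across the portion of the row lying in
    each cell column. This is the oracle the Monte-Carlo cell counts are
    checked against.
    """
    spec.validate(detectable=False)
    cell_um = cell_size_mm * 1000.0
    ny = math.ceil(spec.height_um / cell_um)
    nx = math.ceil(spec.width_um / cell_um)
    out = np.zeros((ny, nx))
    x_lo, x_hi = _row_x_extent(spec)
    if x_hi <= x_lo:
        return out
    for _, y_um in _plantable_rows(spec):
        r = min(int(y_um / cell_um), ny - 1)
        for c in range(nx):
            seg_lo = max(x_lo, c * cell_um)
            seg_hi = min(x_hi, (c + 1) * cell_um)
            if seg_hi <= seg_lo:
                continue
            d_mid = float(_density_at(spec, 0.5 * (seg_lo + seg_hi)))
            out[r, c] += d_mid * spec.file_spacing_um * 1e-6 * (seg_hi - seg_lo)
    return out
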