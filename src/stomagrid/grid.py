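"""1 mm^2 density gridding, fixed-scale heatmaps and grid CSV round-trip.

The leaf extent is tiled from the image origin with half-open square cells;
stomata are assigned by centroid, and each cell's density is its count over
its *available* (non-excluded, in-extent) area. Cells with less than half a
cell of available area are flagged invalid — partial border slivers would
otherwise report inflated densities — and carry no density value at all
(not zero).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import ExclusionMask, StomaSet

DEFAULT_HEATMAP_SCALE = (0.0, 150.0)
DEFAULT_MIN_AVAILABLE_FRAC = 0.5


@dataclass
class DensityGrid:
    """Per-cell stomatal densities over a regular grid.

    ``sd`` holds stomata per mm^2 where ``valid``, NaN elsewhere. ``counts``
    and ``available_area_mm2`` are None for grids loaded from bare density
    matrices (e.g. deposited CSV outputs), which carry no per-cell context.
    ``meta`` carries group labels (genotype, surface, position, replicate).
    """

    sd: np.ndarray
    valid: np.ndarray
    cell_size_mm: float = 1.0
    counts: np.ndarray | None = None
    available_area_mm2: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sd = np.asarray(self.sd, np.float64)
        self.valid = np.asarray(self.valid, bool)
        if self.sd.shape != self.valid.shape or self.sd.ndim != 2:
            raise ValueError("sd and valid must be 2-D arrays of equal shape")
        if self.cell_size_mm <= 0:
            raise ValueError("cell_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sd.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def values(self) -> np.ndarray:
        """Densities of valid cells, row-major."""
        return self.sd[self.valid]

    def mean_density(self) -> float:
        return float(self.values().mean())

    def sd_nan(self) -> np.ndarray:
        """Density matrix with NaN in invalid cells."""
        out = self.sd.copy()
        out[~self.valid] = np.nan
        return out


def grid_density(
    stomata: StomaSet,
    mask: ExclusionMask | None,
    image_extent_um: tuple[float, float],
    cell_size_mm: float = 1.0,
    min_available_frac: float = DEFAULT_MIN_AVAILABLE_FRAC,
    meta: dict | None = None,
) -> DensityGrid:
    """Grid detections into half-open cells anchored at the image origin.

    ``image_extent_um`` is (width, height) in micrometres. Available area is
    the cell area minus excluded and out-of-extent area; cells below
    ``min_available_frac`` of a full cell are invalid.
    """
    w_um, h_um = image_extent_um
    cell_um = cell_size_mm * 1000.0
    if w_um < cell_um or h_um < cell_um:
        raise ValueError("image extent smaller than one grid cell")
    nx = math.ceil(w_um / cell_um)
    ny = math.ceil(h_um / cell_um)

    counts = np.zeros((ny, nx))
    pts = stomata.centroids_um
    if len(pts):
        cx = np.floor(pts[:, 0] / cell_um).astype(int)
        cy = np.floor(pts[:, 1] / cell_um).astype(int)
        ok = (cx >= 0) & (cx < nx) & (cy >= 0) & (cy < ny)
        np.add.at(counts, (cy[ok], cx[ok]), 1)

    if mask is not None:
        px = mask.pixel_size_um
        H, W = mask.mask.shape
        row_cell = np.minimum(((np.arange(H) + 0.5) * px / cell_um).astype(int), ny - 1)
        col_cell = np.minimum(((np.arange(W) + 0.5) * px / cell_um).astype(int), nx - 1)
        avail_px = np.zeros((ny, nx))
        np.add.at(avail_px, (row_cell[:, None], col_cell[None, :]), ~mask.mask)
        available = avail_px * px**2 / 1e6
    else:
        # analytic overlap of each cell with the extent rectangle
        x_edges = np.arange(nx + 1) * cell_um
        y_edges = np.arange(ny + 1) * cell_um
        wx = np.clip(np.minimum(x_edges[1:], w_um) - x_edges[:-1], 0, None)
        wy = np.clip(np.minimum(y_edges[1:], h_um) - y_edges[:-1], 0, None)
        available = np.outer(wy, wx) / 1e6

    valid = available >= min_available_frac * cell_size_mm**2
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.where(valid, counts / available, np.nan)
    return DensityGrid(sd, valid, cell_size_mm, counts, available, meta or {})


def render_heatmap(
    grid: DensityGrid,
    scale: tuple[float, float] = DEFAULT_HEATMAP_SCALE,
    cmap: str = "Spectral_r",
    autoscale: bool = False,
) -> tuple[np.ndarray, list[list[str]]]:
    """Per-cell RGBA colours on a FIXED colour scale plus numeric annotations.

    The default 0-150 stomata mm^-2 span keeps heatmaps comparable across
    leaves; ``autoscale`` rescales to the grid's own range for other data.
    Invalid cells render neutral grey with empty annotation.
    """
    import matplotlib as mpl

    lo, hi = scale
    if autoscale and grid.n_valid:
        lo, hi = float(grid.values().min()), float(grid.values().max())
        if hi == lo:
            hi = lo + 1.0
    cm = mpl.colormaps[cmap]
    norm = np.clip((grid.sd - lo) / (hi - lo), 0.0, 1.0)
    norm = np.where(grid.valid, norm, 0.0)
    rgba = cm(norm)
    rgba[~grid.valid] = (0.85, 0.85, 0.85, 1.0)
    ann = [
        [
            str(int(round(grid.sd[r, c]))) if grid.valid[r, c] else ""
            for c in range(grid.shape[1])
        ]
        for r in range(grid.shape[0])
    ]
    return rgba, ann


def save_heatmap_png(
    grid: DensityGrid,
    path: str | Path,
    scale: tuple[float, float] = DEFAULT_HEATMAP_SCALE,
    cmap: str = "Spectral_r",
    autoscale: bool = False,
    cell_inches: float = 0.35,
) -> None:
    """Render the heatmap with per-cell numbers in the top-left corners."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgba, ann = render_heatmap(grid, scale, cmap, autoscale)
    ny, nx = grid.shape
    fig, ax = plt.subplots(figsize=(max(nx * cell_inches, 2), max(ny * cell_inches, 2)))
    ax.imshow(rgba, interpolation="nearest")
    for r in range(ny):
        for c in range(nx):
            if ann[r][c]:
                ax.text(c - 0.45, r - 0.30, ann[r][c], fontsize=6, va="top", ha="left")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def write_grid_csv(grid: DensityGrid, path: str | Path) -> None:
    """Density matrix as CSV (empty field = invalid cell) + sidecar JSON.

    The sidecar (``<path>.json``) carries cell size, group labels and, when
    present, the per-cell counts and available areas, so the round trip is
    lossless.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for r in range(grid.shape[0]):
            w.writerow(
                [
                    repr(float(grid.sd[r, c])) if grid.valid[r, c] else ""
                    for c in range(grid.shape[1])
                ]
            )
    side = {
        "cell_size_mm": grid.cell_size_mm,
        "meta": grid.meta,
        "counts": None if grid.counts is None else grid.counts.tolist(),
        "available_area_mm2": None
        if grid.available_area_mm2 is None
        else grid.available_area_mm2.tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(side))


def read_grid_csv(path: str | Path) -> DensityGrid:
    """Read a density matrix CSV (optionally with its sidecar JSON)."""
    path = Path(path)
    rows: list[list[float]] = []
    valid_rows: list[list[bool]] = []
    with open(path, newline="") as fh:
        for i, rec in enumerate(csv.reader(fh)):
            if not rec:
                continue
            vals, flags = [], []
            for j, tok in enumerate(rec):
                tok = tok.strip()
                if tok == "":
                    vals.append(np.nan)
                    flags.append(False)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: non-numeric cell {tok!r} at row {i + 1}, column {j + 1}"
                        ) from exc
                    flags.append(True)
            if rows and len(vals) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged matrix — row {i + 1} has {len(vals)} fields, "
                    f"expected {len(rows[0])}"
                )
            rows.append(vals)
            valid_rows.append(flags)
    if not rows:
        raise ValueError(f"{path}: empty grid file")
    sd = np.array(rows)
    valid = np.array(valid_rows)
    cell, meta, counts, avail = 1.0, {}, None, None
    side = Path(str(path) + ".json")
    if side.exists():
        info = json.loads(side.read_text())
        cell = info.get("cell_size_mm", 1.0)
        meta = info.get("meta", {})
        counts = None if info.get("counts") is None else np.array(info["counts"])
        avail = (
            None
            if info.get("available_area_mm2") is None
            else np.array(info["available_area_mm2"])
        )
    return DensityGrid(sd, valid, cell, counts, avail, meta)
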