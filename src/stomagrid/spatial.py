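"""Spatial heterogeneity statistics on gridded stomatal densities.

Two complementary views of a density grid: the relative global deviation
(how far each 1 mm^2 cell sits from its group mean, unitless so genotypes of
different density can be compared) and Moran's I spatial autocorrelation
(whether similar densities cluster) over binary k-nearest-neighbour weights.

The global statistic is

    I = n/W * sum_i sum_j w_ij z_i z_j / sum_i z_i^2,      z_i = SD_i - SDbar

and the local statistic is kept in its unnormalised product form

    I_i = z_i * sum_j w_ij z_j

so that the identity ``I = (n/W) * sum_i I_i / sum_i z_i^2`` is exact.
Weights are binary and directed (each valid cell points at its k nearest
valid cells; no row standardisation — the n/W prefactor in the formula
would be redundant under it). Invalid cells take no part in n, W, SDbar or
any sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DensityGrid


class UndefinedStatisticError(ValueError):
    """The statistic is undefined on this input (e.g. zero variance)."""


@dataclass
class SpatialWeights:
    """Binary directed k-NN weights over the valid cells of one grid.

    ``cells`` lists the (row, col) of each valid cell in row-major order;
    ``neighbours[i]`` holds the k indices (into ``cells``) of cell i's
    nearest valid neighbours.
    """

    cells: np.ndarray  # (n, 2) int
    neighbours: np.ndarray  # (n, k) int
    k: int

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def W(self) -> float:
        """Sum of all weights; n*k for binary directed k-NN."""
        return float(self.n * self.k)


@dataclass
class DeviationMaps:
    """Absolute and relative global deviation of each cell from the group mean."""

    d_abs: np.ndarray
    d_rel: np.ndarray
    d_signed: np.ndarray  # retained for diagnostics (deviation with sign)
    mean_d_rel: float
    cv_percent: float


@dataclass
class MoranResult:
    global_i: float
    local_i: np.ndarray
    mean_local_i: float
    k: int
    meta: dict


def knn_weights(grid: DensityGrid, k: int = 4) -> SpatialWeights:
    """k nearest valid cells by Euclidean distance between cell centres.

    Distance ties are broken by row-major cell index, so the weights are
    deterministic on perfectly regular lattices (where, e.g., a corner cell
    sees several candidates at equal distance).
    """
    cells = np.argwhere(grid.valid)
    n = len(cells)
    if n <= k:
        raise UndefinedStatisticError(
            f"need more than k={k} valid cells to build k-NN weights (got {n})"
        )
    centres = (cells + 0.5) * grid.cell_size_mm
    d2 = ((centres[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)  # no self-neighbours
    idx = np.arange(n)
    neighbours = np.empty((n, k), int)
    for i in range(n):
        order = np.lexsort((idx, d2[i]))
        neighbours[i] = order[:k]
    return SpatialWeights(cells, neighbours, k)


def relative_global_deviation(grid: DensityGrid) -> DeviationMaps:
    """|SD_rc - SDbar| and its group-mean-normalised (unitless) form.

    SDbar is the mean over the grid's valid cells — the "group" is whatever
    the grid represents (one genotype x position x surface x replicate
    matrix, or a pooled matrix built upstream).
    """
    vals = grid.values()
    if vals.size == 0:
        raise UndefinedStatisticError("no valid cells")
    mean = vals.mean()
    if mean <= 0:
        raise UndefinedStatisticError("group mean density is zero: relative deviation undefined")
    signed = grid.sd - mean
    signed[~grid.valid] = np.nan
    d_abs = np.abs(signed)
    d_rel = d_abs / mean
    cv = coefficient_of_variation(grid) if vals.size >= 2 else float("nan")
    return DeviationMaps(
        d_abs=d_abs,
        d_rel=d_rel,
        d_signed=signed,
        mean_d_rel=float(np.nanmean(d_rel[grid.valid])),
        cv_percent=cv,
    )


def _centered(grid: DensityGrid, weights: SpatialWeights) -> np.ndarray:
    z = grid.sd[weights.cells[:, 0], weights.cells[:, 1]]
    z = z - z.mean()
    if not np.any(z != 0):
        raise UndefinedStatisticError("zero variance across valid cells: Moran's I undefined")
    return z


def global_morans_i(grid: DensityGrid, weights: SpatialWeights) -> float:
    """Global Moran's I: positive = clustering of similar densities,
    negative = dispersion, near zero = spatial randomness."""
    z = _centered(grid, weights)
    num = float((z[:, None] * z[weights.neighbours]).sum())
    return weights.n / weights.W * num / float((z**2).sum())


def local_morans_i(
    grid: DensityGrid, weights: SpatialWeights, standardized: bool = False
) -> MoranResult:
    """Local Moran's I per valid cell, unnormalised product form.

    ``standardized=True`` divides by the variance m2 = sum(z^2)/n, giving the
    conventional LISA scaling; the default matches the plain product form so
    the sum-to-global identity holds exactly.
    """
    z = _centered(grid, weights)
    ii = z * z[weights.neighbours].sum(axis=1)
    if standardized:
        ii = ii / ((z**2).sum() / weights.n)
    local = np.full(grid.shape, np.nan)
    local[weights.cells[:, 0], weights.cells[:, 1]] = ii
    return MoranResult(
        global_i=global_morans_i(grid, weights),
        local_i=local,
        mean_local_i=float(ii.mean()),
        k=weights.k,
        meta=dict(grid.meta),
    )


def coefficient_of_variation(grid: DensityGrid) -> float:
    """100 * sample standard deviation / mean over valid cells, percent."""
    vals = grid.values()
    if vals.size < 2:
        raise UndefinedStatisticError("need >= 2 valid cells for a CV")
    mean = vals.mean()
    if mean <= 0:
        raise UndefinedStatisticError("mean density is zero: CV undefined")
    return float(100.0 * vals.std(ddof=1) / mean)


def aggregate_replicates(maps: list[np.ndarray], min_valid_frac: float = 0.5) -> np.ndarray:
    """Cell-wise median across replicate maps (NaN = invalid cell).

    Maps are aligned at their top-left valid anchor (the minimum valid row
    and column), cropped to the common intersection shape, and the median
    ignores invalid cells. An output cell is valid (non-NaN) where at least
    ``min_valid_frac`` of the replicates are valid.
    """
    if not maps:
        raise ValueError("need at least one map")
    shifted = []
    for m in maps:
        m = np.asarray(m, np.float64)
        ok = np.isfinite(m)
        if not ok.any():
            raise ValueError("a replicate map has no valid cells")
        r0 = int(np.argwhere(ok)[:, 0].min())
        c0 = int(np.argwhere(ok)[:, 1].min())
        shifted.append(m[r0:, c0:])
    ny = min(m.shape[0] for m in shifted)
    nx = min(m.shape[1] for m in shifted)
    if ny == 0 or nx == 0:
        raise ValueError("empty intersection after alignment")
    stack = np.stack([m[:ny, :nx] for m in shifted])
    n_ok = np.isfinite(stack).sum(axis=0)
    with np.errstate(all="ignore"):
        med = np.nanmedian(stack, axis=0)
    med[n_ok < min_valid_frac * len(maps)] = np.nan
    return med
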