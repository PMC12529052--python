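"""Monte Carlo sampling-sufficiency simulation and sampling-regime regressions.

How many 1 mm^2 cells must be sampled before the sample mean density is a
reliable estimate of the leaf's true mean? For every sample size n the
simulator draws cells without replacement, records the error of the sample
mean and whether the t-based 95% confidence interval covers the population
mean, and the minimum sampling requirement is the smallest n that meets
both an error ceiling and a coverage floor simultaneously.

The regime regressions quantify how sampling intensity attenuates
structure-function relationships: stomatal conductance is regressed on
densities averaged over small / medium / large numbers of sampled cells,
with Benjamini-Hochberg adjustment across the regression family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import DensityGrid

DEFAULT_ITERATIONS = 1000
DEFAULT_MAX_REL_ERR = 0.10
DEFAULT_MIN_COVERAGE = 0.95

#: Sampling regimes in whole 1 mm^2 cells: (min_cells, max_cells); None = all.
DEFAULT_REGIMES: dict[str, tuple[int, int | None]] = {
    "small": (1, 3),
    "medium": (10, 30),
    "large": (50, None),
}


@dataclass
class PerSampleSizeStats:
    """Aggregates of one sample size's Monte Carlo iterations."""

    n: int
    mean_sd_of_samples: float  # mean over iterations of the sample mean
    sd_of_samples: float  # spread of the sample means across iterations
    mean_abs_error: float
    mean_rel_error: float
    mean_se: float
    ci_coverage: float


@dataclass
class SamplingSimResult:
    """Per-sample-size statistics and the derived minimum requirement."""

    stats: pd.DataFrame  # one row per n, columns as PerSampleSizeStats
    population_mean: float
    n_population: int
    iterations: int
    seed: int
    meta: dict = field(default_factory=dict)

    def row(self, n: int) -> pd.Series:
        return self.stats.loc[self.stats["n"] == n].iloc[0]


@dataclass
class MinSamplingRequirement:
    n_min: int | None  # None = no sample size qualifies
    fraction_of_population: float | None
    max_rel_err: float
    min_coverage: float

    @property
    def achievable(self) -> bool:
        return self.n_min is not None


@dataclass
class GasExchangeRecord:
    """One paired gas-exchange observation (precomputed by the instrument)."""

    genotype: str
    surface: str
    position: str
    replicate: str
    A: float  # net CO2 assimilation, umol m^-2 s^-1
    gsw: float  # stomatal conductance to water vapour, mol m^-2 s^-1
    Ci: float | None = None  # intercellular CO2, umol mol^-1
    WUE: float | None = None  # intrinsic water use efficiency, umol CO2 / mol H2O

    def __post_init__(self) -> None:
        if self.WUE is not None and self.gsw <= 0:
            raise ValueError("gsw must be positive when WUE is provided")


def subsample_population(
    values: np.ndarray,
    n: int,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
) -> PerSampleSizeStats:
    """Draw ``iterations`` samples of ``n`` cells without replacement.

    Per iteration: relative error = |mean_sample - mean_pop| / mean_pop and a
    95% CI = mean_sample +/- t_{0.975, n-1} * s / sqrt(n). Coverage is the
    fraction of iterations whose CI contains the population mean; at n = 1 no
    t-interval exists and coverage is recorded as 0.
    """
    values = np.asarray(values, np.float64)
    N = values.size
    if not 1 <= n <= N:
        raise ValueError(f"sample size {n} outside [1, {N}]")
    if not np.all(np.isfinite(values)):
        raise ValueError("population values must be finite")
    mean_pop = values.mean()
    if mean_pop == 0:
        raise ValueError("population mean is zero: relative error undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # n columns of a random permutation per iteration = uniform draw w/o replacement
    u = rng.random((iterations, N))
    take = np.argpartition(u, n - 1, axis=1)[:, :n] if n < N else np.tile(np.arange(N), (iterations, 1))
    samples = values[take]

    means = samples.mean(axis=1)
    abs_err = np.abs(means - mean_pop)
    if n >= 2:
        sds = samples.std(axis=1, ddof=1)
        se = sds / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        covered = (means - tcrit * se <= mean_pop) & (mean_pop <= means + tcrit * se)
        coverage = float(covered.mean())
        mean_se = float(se.mean())
    else:
        coverage = 0.0
        mean_se = float("nan")
    return PerSampleSizeStats(
        n=n,
        mean_sd_of_samples=float(means.mean()),
        sd_of_samples=float(means.std(ddof=1)) if iterations > 1 else 0.0,
        mean_abs_error=float(abs_err.mean()),
        mean_rel_error=float(abs_err.mean() / abs(mean_pop)),
        mean_se=mean_se,
        ci_coverage=coverage,
    )


def simulate_sampling(
    values: np.ndarray,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    meta: dict | None = None,
) -> SamplingSimResult:
    """Run the Monte Carlo subsampling for every sample size 1..N.

    Each sample size uses an independent seeded substream, so results are
    identical whether sizes are evaluated serially or in parallel.
    """
    values = np.asarray(values, np.float64)
    N = values.size
    rows = []
    for n in range(1, N + 1):
        rng = np.random.default_rng([seed, n])
        rows.append(vars(subsample_population(values, n, iterations, rng)))
    return SamplingSimResult(
        stats=pd.DataFrame(rows),
        population_mean=float(values.mean()),
        n_population=N,
        iterations=iterations,
        seed=seed,
        meta=meta or {},
    )


def min_sampling_requirement(
    result: SamplingSimResult,
    max_rel_err: float = DEFAULT_MAX_REL_ERR,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> MinSamplingRequirement:
    """Smallest n meeting BOTH the error ceiling and the coverage floor."""
    df = result.stats
    ok = (df["mean_rel_error"] <= max_rel_err) & (df["ci_coverage"] >= min_coverage)
    if not ok.any():
        return MinSamplingRequirement(None, None, max_rel_err, min_coverage)
    n_min = int(df.loc[ok, "n"].min())
    return MinSamplingRequirement(
        n_min, n_min / result.n_population, max_rel_err, min_coverage
    )


def regime_correlation(
    grids: list[DensityGrid],
    gasx: list[GasExchangeRecord],
    regimes: dict[str, tuple[int, int | None]] | None = None,
    seed: int = 0,
    response: str = "gsw",
) -> pd.DataFrame:
    """Structure-function regressions under different sampling intensities.

    Each gas-exchange record pairs with one grid (same leaf/surface/
    position, in list order). Per regime and pair, a seeded draw picks the
    regime's number of cells from the grid, their mean density is the
    predictor, and the response is regressed on it by OLS. P-values of the
    slopes are Benjamini-Hochberg adjusted across all regimes reported
    together.
    """
    from statsmodels.stats.multitest import multipletests

    if len(grids) != len(gasx):
        raise ValueError("grids and gas-exchange records must pair one-to-one")
    if len(grids) < 3:
        raise ValueError("need at least 3 paired observations for a regression")
    regimes = regimes or DEFAULT_REGIMES
    rows = []
    for ri, (name, (lo, hi)) in enumerate(regimes.items()):
        xs, ys = [], []
        for pi, (grid, rec) in enumerate(zip(grids, gasx)):
            vals = grid.values()
            N = vals.size
            hi_eff = N if hi is None else min(hi, N)
            lo_eff = min(lo, N)
            rng = np.random.default_rng([seed, ri, pi])
            n_cells = int(rng.integers(lo_eff, hi_eff + 1))
            take = rng.choice(N, size=n_cells, replace=False)
            xs.append(float(vals[take].mean()))
            ys.append(getattr(rec, response))
        fit = stats.linregress(xs, ys)
        rows.append(
            {
                "regime": name,
                "n_pairs": len(xs),
                "cells_min": lo,
                "cells_max": hi,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
                "p_value": fit.pvalue,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (statsmodels fdr_bh)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
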