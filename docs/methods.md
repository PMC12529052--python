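# Methods

This note documents the models, parameter choices and numerical conventions
behind `stomagrid`, and what the synthetic benchmark does and does not show
about real leaf images.

## Imaging model and preprocessing

The unit of processing is a calibrated single-channel raster (`Image2D`),
8- or 16-bit, with a physical pixel pitch (default 1.11 µm/px, the working
resolution of a 4× widefield objective with a 1.5× tube zoom on a large
sCMOS sensor). Multi-plane acquisitions are collapsed by per-pixel maximum
projection before anything else, because leaf segments are never perfectly
planar and the fluorescence signal of interest is the brightest in-focus
plane.

Preprocessing is contrast-limited adaptive histogram equalization followed
by a circular median filter.

* **CLAHE** — block size 127 px, 256 histogram bins, and a transfer-function
  slope bounded to [8, 14] with a working value of 11 (the midpoint).
  The slope s is the histogram clip level expressed as a multiple of the
  uniform bin height; it maps onto `skimage.exposure.equalize_adapthist`
  as `clip_limit = s / nbins` (skimage clips each tile histogram at
  `clip_limit × tile_pixels`). The fast tile-interpolated variant is used:
  transfer functions are evaluated per block and bilinearly interpolated
  in between. All three values are exposed because optimal settings depend
  on leaf and image quality. Processing is float internally and
  re-quantised to the input bit depth, so downstream 256-bin histogram
  thresholds always see the native intensity range. A perfectly flat image
  is passed through unchanged (single-bin histograms have no contrast to
  equalise).
* **Median filter** — "size 8" is interpreted as a circular neighbourhood
  of radius 8 px (the convention of the interactive toolchain this
  workflow descends from), with replicated edges. For integer images the
  filter runs through an in-package Huang sliding-histogram kernel with a
  coarse/fine two-tier histogram (numba-compiled); it is bit-identical to
  `scipy.ndimage.median_filter` with the same disk footprint (the test
  suite verifies this and a brute-force sort oracle) but roughly an order
  of magnitude faster on multi-megapixel leaf scans, which keeps
  whole-pipeline runs on centimetre-scale images in the seconds-per-image
  range. Float inputs fall back to scipy.

## Detection

Stomata are non-fluorescent on a fluorescing mesophyll, so all thresholds
keep the **dark** side. Thresholding uses the classic 256-bin histogram
convention regardless of bit depth.

Three auto-thresholds are applied independently to the same preprocessed
image: **Li** (minimum cross-entropy fixed point), **Moments** (Tsai's
moment-preserving bilevel threshold) and **Minimum** (the valley between
the two modes of an iteratively mean-smoothed histogram; it fails
explicitly, and is skipped, when the histogram never becomes bimodal).
Li and Minimum are implemented from the histogram and cross-checked in the
tests against `skimage.filters.threshold_li` / `threshold_minimum`;
Moments is implemented in-package (no installed library provides it) and
checked against an independent quadratic-root oracle.

Each binary is measured by 8-connected component analysis
(`skimage.measure`): area = pixel count × pixel area, centroid = unweighted
pixel centroid, circularity = 4πA/P² with a Crofton 4-direction perimeter.
The Crofton estimator approximates the smoothed-perimeter convention the
published 0.5–0.9 circularity gate assumes; it is worth knowing that a
*digital disk* scores ≈ 0.96 under it — the gate genuinely expects
elliptical stomatal complexes (a 2.4:1 ellipse scores ≈ 0.76), and the
estimator is therefore documented as part of the gate's meaning. Area gates
are 800–4000 µm² (Moments, Li) and 800–3000 µm² (Minimum), inclusive.

"Iterative thresholding" is realised as union-with-merge: the per-rule
particle lists are pooled in the order Moments, Li, Minimum and detections
whose centroids fall within 25 µm (≈ half a stomatal major axis) of an
already-kept detection are dropped, keeping the earliest rule's detection.
An alternative reading — removing detected particles from the image between
passes — changes the later thresholds' histograms and was not adopted; the
union is order-independent in count up to distance ties.

**Exclusion mask.** Regions that cannot bear stomata (veins, leaf border,
degraded tissue) are found by Percentile thresholding (smallest histogram
bin whose cumulative fraction reaches 0.5 — the classic default; ties go to
the smaller bin) and keeping dark components larger than 400 000 µm².
These components are **4-connected**, deliberately differing from the
8-connectivity of particle analysis: the 50th-percentile cut also leaves
roughly 40–50 % of the *background* pixels dark, and a random field at that
density percolates into spurious image-spanning components under
8-connectivity (site threshold ≈ 0.407) but stays fragmented under
4-connectivity (threshold ≈ 0.593), while solid vein stripes and border
frames remain single large components either way. A detection is discarded
when its centroid pixel lies on the mask (centroid rule, not any-overlap:
simple and testable). Stomatal density is
`n / ((total − excluded) / 10⁶)` stomata mm⁻², undefined when no area
remains.

## Density grid

The image extent is tiled from the origin with half-open 1 mm² cells
(configurable); stomata are assigned by centroid, so no stoma is counted
twice. Each cell's available area is its in-extent, non-excluded area;
cells below 50 % available area are flagged **invalid** and carry no
density (not zero) — partial border slivers would otherwise report inflated
or deflated densities. The 50 % cutoff is this package's rule for partial
cells and is configurable. Heatmaps use a *fixed* 0–150 mm⁻² spectral
(blue→red) scale by default so leaves are comparable; autoscaling is an
explicit flag for other species. Grid CSVs store the density matrix with
empty fields for invalid cells, plus a JSON sidecar with cell size, group
labels and (when known) per-cell counts and available areas, making the
round trip lossless.

## Spatial statistics

For a group's density matrix with mean S̄D over valid cells and
z_i = SD_i − S̄D:

* relative global deviation: D_rc = |SD_rc − S̄D|, D_rc_rel = D_rc / S̄D —
  the absolute value follows the metric's "absolute deviation" definition;
  the signed map is retained for diagnostics. Scale-invariant by
  construction. The group mean is always the mean of the matrix being
  analysed; pooling across replicates is done by the caller.
* coefficient of variation: 100 × sample SD / mean (ddof = 1).
* Moran's I over binary, **directed**, non-row-standardised k-NN weights
  (k = 4, Euclidean distances between valid cell centres, distance ties
  broken by row-major index). Row standardisation is deliberately not
  applied: the global formula carries the explicit n/W prefactor, which
  row standardisation would make redundant. Local I_i = z_i Σ_j w_ij z_j is
  kept in its plain product form — *not* divided by the variance m₂ as the
  conventional LISA is — so the identity I = (n/W) Σ I_i / Σ z² holds
  exactly (verified to 1e-12); the standardised variant is available behind
  an off-by-default flag. Zero-variance grids raise an explicit
  undefined-statistic error rather than returning 0 or NaN. Invalid cells
  are removed from n, W, S̄D and every sum.
* replicate aggregation: maps are aligned at their top-left valid anchor,
  cropped to the common intersection, and combined by cell-wise median;
  an output cell is valid where at least half the replicates are.

Under random permutation of cell values the global statistic has
expectation −1/(n−1); the suite checks this to 3 Monte Carlo standard
errors over 2000 permutations.

## Sampling simulation

For every sample size n from 1 to N (valid cells of one group matrix), 1000
seeded draws without replacement record the sample mean, its deviation from
the population mean (relative error uses the same matrix's mean — the
"true" mean of that population), and whether the 95 % t-interval
mean ± t₀.₉₇₅,ₙ₋₁·s/√n covers it. n = 1 has no t-interval and scores
coverage 0, which reproduces the two-cell floor of the minimum sampling
requirement without special-casing; for a constant population the
zero-width interval centred on the mean covers it, so n_min = 2 exactly.
The minimum sampling requirement is the smallest n meeting ≤ 10 % mean
relative error *and* ≥ 95 % coverage simultaneously; if none qualifies an
explicit not-achievable result is returned. Each n uses an independent
seeded substream, so serial and parallel evaluation agree bitwise.

Calibration note: the t-interval ignores the finite-population correction,
so its coverage is nominal (0.95) only while the sampling fraction is small;
as n → N the interval becomes conservative and coverage climbs to 1. The
calibration test therefore checks the [0.93, 0.97] band for n up to N/10.
The mean relative error follows c/√n over the same regime (R² > 0.95 for
n ≤ N/2).

Sampling regimes for the structure–function regressions are whole cells:
small = 1–3, medium = 10–30, large = 50+ cells (half-cells are not
representable in gridded matrices, so the sub-1 mm² end of the small regime
is mapped to one cell). Per regime and grid/gas-exchange pair, a seeded
draw fixes the cell count, the sampled cells' mean density is the
predictor, and g_sw (or another response) is fitted by OLS; slope p-values
are Benjamini–Hochberg adjusted across all regressions reported together
(statsmodels `fdr_bh`). Gas-exchange quantities (A, g_sw, C_i, WUE) arrive
precomputed — deriving them from raw analyzer signals is out of scope.

## Synthetic leaf generator

The generator emulates the features the pipeline must cope with and
nothing more: bright mesophyll with multiplicative Gaussian speckle
(sd 15 % of the mean) blurred with a σ = 1.5 px Gaussian to mimic texture;
dark elliptical stomata at 25 % of the background mean; dark longitudinal
vein stripes (default three, 150 µm wide — above the 400 000 µm² exclusion
cutoff over a 4 mm span) and a 150 µm dark border frame, both rendered at
stomatal intensity so exclusion masking is genuinely exercised.

Stomata sit on files every 100 µm. Along a file they follow a stationary
renewal process: gap = hard-core + Exponential(θ(x)), with θ(x) chosen so
the local mean spacing equals 1/(density(x) · file spacing), giving a
linear base→tip density gradient; the first point is drawn from the
forward-recurrence distribution so edge cells are not under-populated, and
`expected_count_field` integrates the same rate analytically as the oracle
for Monte-Carlo cell counts. The hard core is the stomatal major axis plus
a 25 µm clearance. The clearance is deliberate: it is the generator's
one-cell-spacing analogue, and it guarantees that neighbouring stomata
remain resolvable after the radius-8 median filter (a 17 px ≈ 19 µm
kernel), which would otherwise bridge touching ellipses into single
particles that no parameterisation of the published gates could split.
Densities above ~117 mm⁻² at the default spacing are rejected as
infeasible, as are gradients touching zero at one end (the renewal rate
must stay positive); zero density at both ends renders an empty leaf.

Default geometry: stomata 60 × 25 µm (area ≈ 1178 µm², Crofton circularity
≈ 0.75 — comfortably inside every gate), densities 60 → 90 mm⁻²
(tip : base ≈ 1.5, the gradient magnitude typical of a cereal flag leaf),
16-bit output at 45 % of full scale. The stomatal contrast (25 % of
background) was chosen once, empirically, as a level at which the printed
thresholds separate the intensity modes cleanly; no quantitative contrast
is available to copy. All randomness derives from one seed with per-file
sub-streams plus a dedicated speckle stream, so identical spec + seed is
bit-identical regardless of evaluation order.

**What passing the synthetic benchmark does not show.** The generator has
no optical PSF, no tile-stitching seams, no dumbbell guard-cell
morphology, no degraded-tissue patches, no focus gradients and no
autofluorescent dust/fibre clutter. Detection recall ≈ 99 % on synthetic
leaves therefore demonstrates the correctness of the chain (thresholds,
gates, masking, matching), not the field performance on real micrographs,
where published-style validation against manual counts (the
`validate_against_truth` greedy matcher at 25 µm) remains necessary. On
empty blurred-speckle fields the detector produces a small number of
spurious particles (~2 per mm² at default noise); on structured leaves the
thresholds lock onto the true dark mode and precision stays ≈ 0.99.

## Numerical conventions and degenerate inputs

Pixel indices are 0-based, origin top-left, x = column; physical
coordinates are centroid × pixel size. Threshold binaries keep bins ≤ t.
Greedy validation matching visits truth points in row-major order and
claims the nearest unclaimed detection within 25 µm. Empty detection sets
give recall 0 and precision 0 with a warning. All statistics raise typed
errors on degenerate inputs (zero variance, zero mean, too few valid
cells) instead of returning silent NaNs.

## Problem sizes used in the shipped checks

The validation scripts and tests use 2 × 2 to 4 × 4 mm synthetic leaves
(roughly 3.2–13 Mpx at 1.11 µm/px) with 600–1100 stomata each — large
enough that every stage (tile-interpolated CLAHE, exclusion percolation
behaviour, 1 mm² gridding) operates in its intended regime, while a full
ten-leaf validation sweep completes in a few minutes on one CPU. Sampling
calibration uses a 400-cell Gaussian population (µ = 80, σ = 20 mm⁻²),
matching the size of a typical per-leaf matrix.

## Known limitations

* Single cell type: no epidermal pavement-cell or subsidiary-cell
  quantification, no aperture measurement.
* Axis-aligned rectangular extents only; no leaf straightening.
* The Minimum threshold can fail on low-contrast images (by design it
  reports failure rather than guessing); detection then rests on Moments
  and Li.
* The exclusion percentile (0.5) is the classic default; the workflow the
  method descends from does not print the exact fraction, and strongly
  atypical dark-area fractions may warrant adjusting it.
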