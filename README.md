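# stomagrid

Large-area stomatal density mapping from chlorophyll-autofluorescence leaf
images.

Stomata — the pores through which a leaf trades CO₂ uptake against water
loss — are conventionally counted on epidermal peels or impressions covering
≤ 1 mm² of leaf. At that scale the substantial spatial heterogeneity of
stomatal density (SD) across a grass leaf is invisible, and SD–physiology
correlations built on such samples are unreliable. Under blue excitation the
chlorophyll-rich mesophyll fluoresces while stomatal guard cells do not, so
in an autofluorescence micrograph stomata appear as dark ellipses arranged
in longitudinal files. `stomagrid` turns such images (centimetre-scale,
stitched, 16-bit, ~1.11 µm/px) into:

1. **per-stoma detections** — CLAHE + median preprocessing, then three
   auto-thresholds (Moments, Li, Minimum) applied to the dark side of the
   histogram, each followed by particle filtering (area 800–4000 µm²,
   or 800–3000 µm² for Minimum; circularity 4πA/P² in 0.5–0.9) and pooled
   with a 25 µm de-duplication radius;
2. **an exclusion mask** of regions that cannot bear stomata (veins, leaf
   edges, degraded tissue): Percentile-thresholded dark components larger
   than 400 000 µm². SD = stomata / (total − excluded area);
3. **a 1 mm² density grid** (SD_rc per cell against per-cell available
   area) rendered as a fixed-scale 0–150 mm⁻² heatmap;
4. **spatial statistics**: the relative global deviation
   `D_rc_rel = |SD_rc − S̄D| / S̄D`, the coefficient of variation, and
   global/local Moran's I over binary k-nearest-neighbour weights (k = 4),

   `I = n/W · ΣᵢΣⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ²`, `Iᵢ = zᵢ Σⱼ wᵢⱼ zⱼ`, `zᵢ = SDᵢ − S̄D`;
5. **sampling-sufficiency analysis**: 1000-iteration Monte Carlo
   subsampling without replacement at every sample size, reporting relative
   error and t-interval coverage, the minimum number of 1 mm² cells meeting
   ≤ 10 % mean relative error and ≥ 95 % CI coverage, and OLS regressions of
   stomatal conductance (g_sw) on SD under small/medium/large sampling
   regimes with Benjamini–Hochberg adjustment.

A seeded synthetic-leaf generator (`stomagrid.synthetic`) renders
autofluorescence-style images — elliptical stomata in parallel files with a
base→tip density gradient, dark veins and border, multiplicative speckle —
together with exact ground truth, so the entire chain is testable without a
microscope.

It is aimed at plant phenotyping groups quantifying stomatal patterning in
cereals (or any species with file-ordered stomata) and at method developers
who need a ground-truthed benchmark for stomate detectors.

## Worked example

Simulate a 3 × 2 mm leaf with a 60 → 90 mm⁻² base-to-tip gradient, run the
default pipeline, and score it against the generator's ground truth:

```
$ stomagrid simulate --width-mm 3 --height-mm 2 --base-density 60 \
      --tip-density 90 --seed 42 --out-dir demo
193 stomata rendered -> demo
$ stomagrid preprocess --in demo/leaf.tif --out demo/pre.tif
$ stomagrid detect --in demo/pre.tif --out-dir demo/det
{"n_stomata": 192, "total_area_um2": 6001320.07, "excluded_area_um2": 2607957.73,
 "density_mm2": 56.58}
$ stomagrid validate --detections demo/det/detections.csv \
      --truth demo/ground_truth.csv
{"recall": 0.9948, "precision": 1.0, "n_truth": 193, "n_detected": 192}
```

192 of the 193 rendered stomata are recovered (recall 99.5 %) with no false
positives; the overall density (56.6 mm⁻²) is the count divided by the
3.39 mm² of leaf left after subtracting veins and border. Gridding and
spatial statistics:

```
$ stomagrid grid --detections demo/det/detections.csv --image demo/pre.tif \
      --out demo/grid.csv
$ cat demo/grid.csv
45.10,60.71,61.89,
50.41,58.72,61.53,
,,,
$ stomagrid stats --grids demo/grid.csv --out-dir demo/stats
{"global_i": -0.0996, "mean_local_i": -16.19, "mean_d_rel": 0.1021,
 "cv_percent": 12.38}
```

The per-cell densities rise from the base column (~45–50 mm⁻²) toward the
tip (~62 mm⁻²) — the programmed gradient; empty fields are cells with less
than half their area available (border slivers). Global Moran's I near zero
says the six valid cells show no spatial clustering beyond the gradient;
`mean_d_rel` ≈ 0.10 means a cell deviates from the leaf mean by 10 % on
average. `stomagrid run` chains all stages and writes a manifest;
`stomagrid sample-sim` and `stomagrid regime-corr` cover the sampling
analysis. Everything is also available as plain library calls
(`stomagrid.generate_leaf_image`, `detect_stomata`, `grid_density`,
`global_morans_i`, `simulate_sampling`, ...).

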