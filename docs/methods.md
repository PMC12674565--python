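# Methods

## The problem

Bioavailable ⁸⁷Sr/⁸⁶Sr varies across a landscape mainly with the age and
composition of the underlying bedrock: old Rb-rich lithologies (granites,
rhyolites) are radiogenic (high ⁸⁷Sr/⁸⁶Sr), young or Rb-poor ones (basalts,
carbonates) are not. An isoscape is a continuous prediction surface of this
ratio plus an uncertainty surface; comparing archaeological tissue ratios
with the predicted range around a find site classifies samples as local or
non-local. The package implements the full machine-learning isoscape
workflow: covariate extraction, predictor selection, forest and
stacked-ensemble prediction with quantile-based uncertainty, a
sampling-design experiment, and the buffer-based assessment.

## Synthetic landscape generator

The generator (`srscape.synthetic`) produces worlds with the statistical
structure the modelling assumes, not a replica of any real geography:

- **Geology**: a Voronoi tessellation of `n_geology_units` (default 12)
  from uniformly placed seeds — the simplest piecewise-constant surrogate
  with the sharp unit boundaries that make spatial autocorrelation locally
  weak. Unit ages are log-uniform on 10–3000 Myr.
- **Response link**: true ratio = intercept + slope·log₁₀(age Myr) + Σ
  climate terms. Defaults 0.704 + 0.004·log₁₀(age) span ≈ 0.708–0.718,
  the magnitude of a continental-interior survey region; affine-in-log-age
  qualitatively matches the saturating rise of ratio with bedrock age.
- **Climate fields**: Gaussian random fields (white noise smoothed with a
  Gaussian kernel, 20 km correlation length, unit variance) with small
  slopes (8·10⁻⁴, 5·10⁻⁴, 3·10⁻⁴) — smooth environmental modifiers on top
  of the dominant geological signal.
- **Sampling**: half the 500 default sites fall inside one randomly placed
  30 km disc (the densely surveyed "province"), half uniformly — emulating
  a regional campaign appended to a sparse background database. Recorded
  ratio = cell truth + N(0, σ_local) + N(0, σ_meas) with σ_local = 10⁻³
  (within-site field variability; a free simulation parameter, not an
  estimate from data) and σ_meas = 10⁻⁴ (plant-standard external
  reproducibility, ~300 ppm at 2σ).
- Grid: 120×100 cells of ~1 km on geographic WGS84; all randomness flows
  through one seeded generator, so worlds are bit-reproducible.

What the generator does **not** emulate: weathering/mixing geochemistry,
rainfall and dust Sr budgets, anisotropic geology, coordinate error, or
material-dependent offsets between plants, soils and tissues. Passing
tests therefore demonstrate that the *algorithms* recover a known truth
under the stated noise model — not that any real-region isoscape is
accurate.

## Covariates

Extraction takes the value of the containing cell; a nodata hit falls back
to the nearest valid cell by great-circle distance within 50 km (the
largest assessment radius; unbounded search would silently import
far-field values) and is flagged `nearest-fallback`. Pruning iteratively
removes one member of the worst pair while any |Pearson R| exceeds 0.9 —
absolute value, since strong negative correlation is equally redundant for
forests. The member dropped is the one with the larger mean absolute
correlation against the remaining predictors (ties: the later column), a
reproducible convention; the report records every removal with its
triggering partner.

## Variable selection

Three steps over a ranking by permutation importance:

1. **Threshold** — `n_forests` (default 50) forests are fit; per-variable
   permutation importance is measured on a held-out third of the data
   (out-of-sample, so pure-noise variables score near zero), and variables
   whose mean importance falls below the minimum of a regression-tree fit
   to the importance-SD-versus-rank curve are discarded. An all-noise
   input yields an explicit empty result, not an exception.
2. **Interpretation** — nested models along the ranking; keep the smallest
   whose mean OOB mean-squared error is within one SD of the minimum
   (`n_forests_nested`, default 25, forests per model).
3. **Prediction** — walk the interpretation set in rank order, admitting a
   variable only if it lowers OOB error by more than the noise-level
   fluctuation, estimated as the mean absolute OOB-error jump along a
   short walk (capped at 8 steps) appending discarded variables.

OOB error is MSE on the ratio scale throughout. The defaults follow the
published three-step procedure's shape; all counts are explicit arguments.

## Forest isoscape and quantile uncertainty

`RandomForestRegressor` with bootstrap bagging, ⌊p/3⌋ split candidates and
3000 trees by default. CV is 10-fold repeated 5 times; RMSE is pooled over
folds and R² = 1 − SSE/SST on held-out predictions (it can be negative;
both OOB and CV-pooled flavours are available since "R²" is ambiguous for
CV). Importance is node-impurity based, normalised to sum to 1; partial
dependence sweeps one covariate over its training range with all rows
otherwise unchanged.

Uncertainty uses the quantile-regression-forest construction on the *same*
forest (one forest, two uses): every training response receives weight
1/(leaf size × n_trees) in each tree whose leaf it shares with the query
point; conditional quantiles are read from the weighted empirical CDF, and
SD = (q₀.₈₄₁₃₄₅ − q₀.₁₅₈₆₅₅)/2, half the 68.27% interval. Two numerical
choices matter:

- **Minimum leaf size 2.** Singleton leaves under-disperse the leaf-weight
  distribution (measured SD ~0.0011 for injected noise 0.002 on a
  one-covariate task); leaves of 5 over-disperse (empirical coverage ~76%
  against nominal 68.27). Leaf size 2 keeps both the interval width and
  the coverage calibrated.
- **Conservatism under model misfit.** Where the forest cannot learn
  residual signal (strong curvature, high signal-to-noise), within-leaf
  signal variation widens the conditional distribution and coverage runs
  ~72–75% — a known property of the method, not an implementation defect.
  Calibration is therefore demonstrated on noise-dominated iid tasks.

Raster prediction processes valid cells in fixed row-major order (chunked;
bit-stable regardless of chunking); any cell missing a covariate is nodata
in both outputs, and predictions are bounded by the training response range
by construction of forest averaging.

## Stacked ensemble

Base learners: random forest, gradient boosting, SVR, a one-hidden-layer
(64) neural network, and cross-validated elastic net. SVR, the network and
the elastic net standardise features *and* target — the ratio's SD (~10⁻³)
is far below their default loss scales (e.g. SVR's ε-tube of 0.1), without
which they degenerate to constants. Sites are projected with a spherical
Lambert azimuthal equal-area projection centred on the data (geographic
degrees are anisotropic), oblique coordinates x·cosθ + y·sinθ for θ ∈ {0°,
45°, 90°, 135°} are appended as covariates, and five spatial CV blocks come
from k-means on the projected coordinates. The meta-learner is fit on
out-of-fold base predictions only and is a *convex* linear combination
(non-negative least squares, weights normalised to 1): unconstrained OLS
weights extrapolate catastrophically under spatially blocked folds, while
the convex combiner keeps the stack inside its base learners' envelope.
Stack CV metrics refit the combiner excluding the evaluated fold, so no
leakage. A base learner that fails to fit is excluded with a warning. The
EML SD surface comes from a quantile forest fit to the same training data
including the oblique features.

## Sampling-effort calibration

Fractions 0–100% in 10% steps of a new regional sample set are drawn
without replacement (10 repeats per fraction), the forest is retrained on
background ∪ drawn, and two quantities are measured at the *remaining*
regional sites: held-out RMSE (accuracy) and mean predicted quantile-forest
SD (precision — the operationalisation of "spatial error", since the
published curve's axis names only "standard deviation"). At 100% there are
no held-out sites; the single evaluation is in-sample and flagged as such.

## Provenance assessment

For each site the prediction raster's min/max over all valid cells whose
*centres* lie within 10/20/50 km great-circle radii (centre-rule raster
buffering; deterministic, no polygon intersection). Within-range is
closed-interval — a boundary-equal sample counts as local. Proportions are
reported per (site, material, epoch class) to two decimals, half-up;
archaeological and modern samples pool separately. The group mean's
deviation from the nearest range bound is bucketed inside / small
(< 0.0005) / moderate / large (> 0.001). Ranges are computed on the
prediction only (not prediction ± SD); interval nesting and proportion
monotonicity across radii are asserted on every run. Sites known only from
per-site summaries keep a `summary_only` flag: proportions are reported
unavailable, the mean-based assessment still runs. Coordinate provenance
(exact / approximated-from-map / averaged) is carried into the report as a
caveat flag.

## Problem sizes in tests and the acceptance script

Forest sizes scale with purpose: 3000 trees is the deployment default, but
CV metrics and raster products stabilise far earlier on the synthetic
worlds, so the analysis scripts use 200–500 trees and the test suite
80–500, with selection run at 10 threshold / 5 nested forests of 100
trees. These are explicit arguments everywhere; the defaults remain the
published configuration.

## Known limitations

- GeoTIFF I/O covers single-band north-up rasters with the standard
  pixel-scale/tiepoint/EPSG GeoKey tags; rotated or tiled-projection
  GeoTIFFs and NetCDF/HDF sources are out of scope (convert first).
- The quantile-forest weight accumulation is O(n_query × n_train) per
  tree; fine for ~10⁴-cell regional grids, not tuned for continental
  rasters.
- No probabilistic (posterior-surface) geographic assignment; the buffer
  ranges are deterministic min/max summaries.
- Spatial blocking is k-means-based; blocks are contiguous but not
  equal-area, and no buffer zone separates blocks from training points.
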