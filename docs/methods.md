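# Methods

This note documents the statistical models, the numerical choices, and the
synthetic experiments behind `rfsp`, in enough detail to judge what the
package's passing tests do and do not establish.

## Data model and conventions

Points carry planar coordinates; all distances are Euclidean in coordinate
units, so geographic (degree) input is accepted but warned about. Grids
are north-up with square cells; the origin is the outer corner of the
top-left cell, cell centers sit at half-cell offsets, and cell membership
is half-open (`[edge, edge + cell_size)`), so every in-extent point maps
to exactly one cell. Overlay is nearest-cell (the value of the containing
cell), not interpolated. Duplicate coordinates are allowed but flagged:
they make zero-nugget kriging systems singular, and `ok_predict` refuses
that combination explicitly rather than jittering silently.

GeoTIFF I/O is implemented on `tifffile`, writing the standard
georeferencing tags (pixel scale, tiepoint, no-data) with one page per
layer and page descriptions as layer names. No reprojection is performed
anywhere; the CRS tag is opaque metadata.

## Variograms and kriging

The empirical variogram is the Matheron method-of-moments estimator on
equal-width lag bins, default maximum lag = half the largest pairwise
distance; coincident pairs are excluded (they estimate measurement error,
not spatial structure). Models (exponential, spherical, Gaussian, pure
nugget; isotropic only) are fitted by weighted least squares with
`N(h)/γ_model(h)²` weights, multi-started from data-driven initials, with
nonnegativity bounds — deterministic and directly checkable against the
estimator, unlike likelihood fitting. Two post-fit conventions matter:

* a fitted range below half the first populated lag is folded into the
  nugget — structure below the data's resolution is unidentifiable from
  noise, and leaving it "structured" randomly corrupts white-noise
  diagnostics;
* the residual-diagnostic quantity is the **expressed structured
  fraction** `(γ(h_max) − γ(h_min))/γ(h_max)` over the observed lag
  window, not raw `psill/(nugget+psill)`. The raw ratio is unidentifiable
  when the fitted range collapses below the first lag or escapes far
  beyond the last one; the expressed fraction correctly scores ~0 in both
  degenerate cases and ~`psill/sill` for genuine in-domain structure.

Ordinary kriging solves the augmented covariance system once per
(global-neighborhood) factorization and handles all targets as one
right-hand-side block; a nearest-m neighborhood is available for large n.
Kriging variances are clipped at zero against round-off. One property
worth stating precisely: a point far beyond the practical range is *not*
screened to zero weight under a global neighborhood — the unbiasedness
constraint always leaves it an O(1/n) mean-estimation weight (the Lagrange
multiplier term). The strict screen property holds exactly under the
nearest-m neighborhood, and that is how the package tests it.

Regression kriging composes OLS trend (with the classical
`MSE·(1 + x₀ᵀ(XᵀX)⁻¹x₀)` prediction variance) and ordinary kriging of the
trend residuals; its reported variance adds the two components without
their cross-term, a documented approximation — the integrated
universal-kriging solver is out of scope. Box–Cox transforms
(`(y^η − 1)/η`, natural log at η = 0) are applied before and inverted
after; at η = 0 the back-transform uses the unbiased log-normal moments
`exp(ŷ_T + σ_T²/2)` and `exp(2ŷ_T + σ_T²)(exp(σ_T²) − 1)`.

## The forest

Base learners are scikit-learn decision trees; everything ensemble-level
is implemented here because QRF needs it explicitly: each tree records its
bootstrap draw (with multiplicity) and the terminal node of every in-bag
sample. Bootstrap draws are with replacement, size
`round(sample_fraction·n)`, with selection probabilities proportional to
case weights; weight-zero observations never enter any draw, and
predictions are provably invariant to their target values. Out-of-bag
statistics average, per observation, the trees whose bootstrap excluded
it. Defaults: 500 trees; mtry = max(1, p/3) for regression and ⌊√p⌋ for
probability; minimal node size 5 (regression) / 10 (probability);
sample_fraction 1. For buffer-distance-only designs the recipes expose
`mtry_fraction`, and ~0.85 is the recommended setting (most distance
layers as split candidates); the same high-mtry advice applies whenever
one or two covariates dominate, e.g. the calendar axes of spatiotemporal
models, because a generic mtry lets splits miss them systematically.

QRF weights follow the original equal-split formulation: within each
tree, every in-bag draw in the prediction point's leaf receives
`1/leaf size`, accumulated per original observation and averaged over
trees; rows sum to 1. Quantiles invert the weighted ECDF by the
lower-step rule (smallest observed y with `F̂ ≥ q`; no interpolation), so
predicted values and quantiles always lie within the training range —
the estimator cannot extrapolate, by construction. The error SD is
`σ_QRF = (ŷ_0.841 − ŷ_0.159)/2` (symmetric-interval assumption); a full
weighted-distribution SD is available behind `sigma_method="sd"` for
skewed conditional distributions. Probability-task forests average leaf
class frequencies; for a binary 0/1 target this is numerically the same
model as a regression forest on the indicator, and the tests confirm the
two agree to a few hundredths.

Multivariate (stacked) models append 0/1 type and method indicator
columns to the design and stack all variables' rows into one matrix;
prediction re-targets the fitted ensemble by setting exactly one type and
one method indicator. Splits on indicators are ordinary numeric splits at
0.5.

## Cross-validation and calibration

`cross_validate` refits the *entire* pipeline per fold: variogram refit,
and buffer-distance layers rebuilt from training-fold points only, so
held-out locations never leak into the covariates (asserted in tests by
checking covariate count = training-fold size). This makes forest CV
k times more expensive than a single fit; that is the price of honest
"with refitting" validation. Folds are random, balanced to within one
point, stratified when labels are given, and deterministic per seed.

Metric conventions: mean error is predicted minus observed; R² uses
`1 − SSE/SST` with SST about the observed mean of the validation points;
Lin's concordance correlation penalizes bias and scale mismatch and never
exceeds |ρ|. z-scores exclude zero-σ points with a count. Accuracy-plot
intervals are symmetric in probability around the median. Only the
z-score summary is reported for calibration scalars; no separate
"standardized accuracy" statistic is defined.

Second-stage sampling is a greedy maximization: take the highest-σ cell,
then repeatedly the next-highest at least `min_spacing` from everything
chosen, ties broken row-major; infeasible requests return the maximal
feasible set with a warning.

## Synthetic data

Gaussian random fields are simulated by dense Cholesky factorization of
the structured covariance over cell centers (jitter `1e-10·sill` on the
diagonal), plus independent nugget noise — exact for any valid covariance
at desk scale; a guard refuses grids above 6 000 cells. Generators for
the study regimes: lognormal transform (skewed concentrations), linear
trends on covariate layers, uniform and parent–offspring clustered
designs, two-source samples with truthfully recorded per-point error SDs,
multinomial class maps as the argmax of K latent fields, and daily
station records built from a seasonal sinusoid plus an AR(1) chain of
spatial fields, left-censored at a threshold to produce zero inflation.
All generators are pure functions of (spec, seed).

What the synthetic experiments do *not* show: behavior under
non-stationarity, anisotropy, strongly non-Gaussian processes beyond the
lognormal/censored constructions, covariate measurement error, or real
sampling biases beyond the simple clustered design. Passing tests
establish internal correctness and calibration under the stated generating
models, not performance on any particular survey.

## Verification experiments and their problem sizes

The benchmark battery (`rfsp.benchmarks`, driven by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) runs at sizes
chosen so the full battery finishes in minutes on one CPU while each
property is measured above its own estimator noise:

* solver agreement: 50 random ≤10-point configurations vs. an independent
  dense solve (agreement ~1e-15);
* exact interpolation, estimator-vs-brute-force, metric identities:
  direct small-n checks;
* log-normal moments: closed form exact; Monte Carlo at 10⁶ draws with
  σ_T² = 0.25 — at σ_T² = 1 the *MC estimator's own* relative SE on the
  variance exceeds 1% because of log-normal kurtosis, so the check is run
  where the oracle is sharper than the tolerance;
* variogram recovery: 20 exponential fields, n = 300;
* z-score calibration: kriging with the true variogram, 10 replicates of
  fivefold CV at n = 150, plus the σ-doubling control (variance → ¼);
* forest vs. kriging: one 40×40 field, n = 150, 300 trees,
  mtry_fraction 0.85 — map correlation and CV-RMSE ratio;
* interval coverage: 200 training / 500 held-out points, nominal levels
  0.1–0.9;
* residual de-correlation: 20 replicates at n = 250 — at n ≈ 150 the
  first-lag bin of the residual variogram has sampling noise of the same
  order as the 0.2 verdict threshold, so the property is evaluated where
  the estimator resolves it;
* case weighting: 20 replicates, two sources with SD ratio 3 (0.4 vs 1.2
  against field SD ≈ 1.05) and weights 1/σ² — weighting only matters when
  the poor source's error variance is comparable to the field's
  variability, which is the measurement-heterogeneity situation the
  mechanism exists for;
* multivariate stacking: strongly cross-correlated field pair (shared
  component 0.85 of variance, field correlation ≈ 0.8), gap averaged over
  3 realizations.

## Known limitations

Isotropic variograms only; no likelihood/REML fitting; RK variance omits
the trend–residual cross-term; no spatiotemporal kriging (only the forest
side of space–time prediction); non-Euclidean distances (cost surfaces,
upslope areas) are not computed but can be supplied as extra layers;
dense-Cholesky simulation and global-neighborhood kriging limit problem
sizes to thousands of cells/points; forest predictions cannot leave the
training range, so genuine extrapolation tasks need a trend model.
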