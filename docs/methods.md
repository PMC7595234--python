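# Methods

`droughtsense` implements a per-pixel analysis of vegetation drought
sensitivity for landscapes observed by annual summer greenness (EVI) and
monthly climate. This note documents the models, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter.

## The sensitivity statistic

For each 1-km pixel, years are classified by the Standardized
Precipitation-Evapotranspiration Index (SPEI) at 3-, 6-, and 12-month
timescales, each anchored at August so the windows cover the June–August
growing season, winter-through-summer, and the full antecedent year.
Classes partition the SPEI axis: severe drought (SPEI ≤ −1.5), moderate
drought (−1.5 < SPEI ≤ −1), baseline (−1 < SPEI < 1), and pluvial
(SPEI ≥ 1). Boundary ties resolve to the dry side.

Drought sensitivity at one timescale and intensity is

    S' = 100 · (EVI_baseline − EVI_drought) / EVI_baseline   [percent]

where `EVI_baseline` is the mean summer EVI over baseline-class years and
`EVI_drought` the mean over moderate- (or severe-) class years. Pluvial
years belong to neither set. The reported statistic `s_mod_max` /
`s_sev_max` is the maximum S' across timescales, with the attaining
timescale recorded. Negative S' (greening under drought) is retained.

Choices, all configurable:

- **Per-timescale baselines.** Each timescale's S' uses its own
  baseline-year set, because per-timescale S' is formed before the max. A
  shared baseline (years baseline under *every* timescale) is available via
  `SensitivityConfig(shared_baseline=True)`.
- **Arithmetic mean** for both numerator terms; median by config.
- **`min_baseline_years=3`, `min_drought_years=1`.** With ~17-year EVI
  records, stricter drought-year minima discard most pixels; a single-year
  drought mean is noisy but usable, and validity flags propagate so
  downstream stages can filter.

## SPEI

The monthly climatic water balance D = P − PET (mm) is summed over the k
months ending at the anchor month, then standardized. Two standardizations
are provided:

- **log-logistic** (default): a three-parameter log-logistic CDF fitted by
  unbiased probability-weighted moments over the calibration period, mapped
  through the inverse standard normal. The moment system is rejected
  (shape β ≤ 1, scale α ≤ 0, or non-finite) on strongly mis-shaped
  samples — most often nearly symmetric ones where the fitted shape
  diverges — and the computation then **falls back to the empirical method
  with a warning**.
- **empirical**: Gringorten plotting positions (r − 0.44)/(n + 0.12)
  through the inverse normal, with monotone linear interpolation and
  end-slope extrapolation so the transform stays strictly increasing for
  values outside the calibration range. CDF values are clipped to
  [1e−6, 1 − 1e−6] before the normal quantile.

Calibration defaults to each pixel's full record; a fixed year range is
configurable. At least 20 calibration years are required (configurable):
below that the distribution fit is too unstable to standardize against.

## Screening

Pixels are excluded before attribution when (a) marked disturbed in the
input mask (fires, insect outbreaks; the synthetic truth table plays this
role in synthetic mode), (b) their EVI series shows a significant
Mann-Kendall monotone trend, or (c) their majority landcover is outside
the modeled ecosystem set. A pixel matching several rules is counted once,
under the first rule in that order, and the exclusion ledger row counts
always sum to the input pixel count.

The Mann-Kendall test uses the tie-corrected variance
n(n−1)(2n+5)/18 − Σ t(t−1)(2t+5)/18, a ±1 continuity correction on S, a
two-sided normal p-value, and the Sen (median pairwise) slope; default
α = 0.05 at n ≥ 8 years. Mann-Kendall + Sen is the standard robust choice
for short annual remote-sensing series; the test family and α are config
options, not claims about any particular prior study's choice.

Cumulative drought exposure is the percent of years in a reference period
(default 1990–2016) whose 12-month August-anchored SPEI is ≤ −1 (any
drought). Both the timescale and the cutoff are configurable.

## Attribution by boosted regression trees

S' is modeled on landscape predictors (elevation, AET, climatic water
deficit, soil available water capacity, soil bulk density, water-table
depth, CTI, HLI, topographic shade density, drought exposure, ecosystem
type) with stagewise least-squares gradient boosting: trees of fixed
complexity (5 splits → `max_leaf_nodes = 6`) fitted to residuals on a
random half of the data per stage (`bag_fraction = 0.5`), predictions
updated by `learning_rate` times the tree output. The boosting engine is
scikit-learn's `GradientBoostingRegressor`; selection, reporting, and the
ensemble protocol are implemented here.

- **Tree-count selection.** Trees are added `step_size = 50` at a time
  while k-fold (default 10) cross-validated squared-error deviance is
  recorded; the count minimizing mean CV deviance is selected, stopping
  after the minimum has not improved for `patience = 5` steps. A minimum
  at `max_trees` triggers a warning to lower the learning rate.
- **Fit statistics.** CV correlation is the Pearson correlation between
  pooled out-of-fold predictions and the response at the selected size;
  percent deviance explained is 100·(1 − pooled out-of-fold MSE / null
  MSE about the mean).
- **Relative influence** is the percent share of total split-wise
  squared-error reduction per predictor (the tree-impurity accrual),
  normalized to sum to 100.
- **Partial dependence** fixes one predictor at each grid value and
  averages model predictions over a reference sample capped at 1,000 rows
  (runtime; cap configurable). Curves are computed between the 5th and
  95th percentiles of the predictor, where tree ensembles are stable;
  the trim bounds travel with the curve.
- **Ensemble protocol.** Default 20 runs, each a random sample of 10,000
  pixels drawn without replacement with a run-specific seed (derived from
  one ensemble seed); products are averaged and IQRs reported on a grid
  shared across runs. Predictors whose median relative influence falls
  below 5% are pruned to form the final model set.
- **Categorical ecosystem codes** are ordinal-integer encoded, so
  influence accrues to the single ecosystem variable rather than being
  split over one-hot columns. With few ordered levels, numeric splits can
  realize any level subset on this encoding in practice; a dedicated
  subset-split search was not implemented.
- The default `learning_rate = 0.005` follows standard BRT practice of
  selecting ensembles of well over 1,000 trees. Tests and the acceptance
  script use faster settings (learning rate 0.05–0.2, tree budgets of a
  few hundred) on datasets of 1,200–10,000 pixels — the selection
  machinery, not the final tree count, is what those runs exercise.

## Synthetic data

The generator produces the statistical endpoints the analysis consumes,
with known truth:

- **Landscape**: each covariate is an independent white-noise field,
  moving-average smoothed over `smoothing_length` pixels (0 = iid) and
  rescaled to a realistic range (e.g. elevation 0–3,000 m, soil bulk
  density 800–1,800 kg/m³). A deficit threshold (450 mm) splits
  shrub-steppe from forest; elevation thresholds assign five ecosystem
  codes. Each pixel carries a subgrid (default 33×33, standing for ~30-m
  cells) of HLI and landcover used for the shade-density / majority /
  mean-CTI aggregation.
- **Truth**: injected moderate-drought sensitivity is linear in
  standardized covariates, clipped to [0, 0.5], with elevation
  (coefficient 0.05) and soil bulk density (0.04) dominant; severe
  sensitivity is 1.3·s_mod + 0.02 clipped to [s_mod, 0.6]. Baseline EVI
  rises linearly with AET over (0.15, 0.65). `make_attribution_dataset`
  adds Gaussian truth noise sized so the linear signal explains a target
  share (default 60%) of response variance.
- **Climate**: monthly precipitation is gamma-distributed (CV 0.5) around
  a winter-peaked seasonal mean (600 mm/yr); PET follows a summer-peaked
  sinusoid (700 mm/yr) with small Gaussian noise. Pixels are independent
  draws from the same regime. Forced-drought years scale precipitation
  over the 12 months ending in August by a configured factor.
- **EVI**: EVI = baseline · (1 − s(class)) · exp(ε), ε ~ N(0, noise_sd²),
  with the class taken from each pixel's own true timescale.
  Multiplicative log-normal noise keeps EVI positive and mimics
  proportional greenness variability. Disturbance is a permanent 40% step
  drop at a uniform-random year; trends add 0.01 EVI/yr by default, sized
  to be detectable by the Mann-Kendall screen at 17 years.

What the generator does **not** emulate: MODIS compositing and atmospheric
artifacts, spatial correlation of climate between pixels, cross-covariate
correlation structure (real terrain couples elevation, deficit, and AET),
phenology, and disturbance recovery trajectories. Passing recovery tests
therefore demonstrates that the pipeline's estimators are correct and
unbiased under the assumed data-generating model, not that the real-data
products are free of compositing or co-registration artifacts.

## Numerical and reproducibility notes

- All generators take explicit integer seeds and are bit-reproducible; the
  pipeline derives stage seeds from one global seed via
  sha256(seed:stage:index), so no stage reuses another's stream.
- Majority-landcover ties resolve to the smallest code; SPEI class
  boundary ties resolve to the dry side; quantiles use linear (type-7)
  interpolation everywhere.
- A degenerate (zero-variance) water-balance series is an error, not a
  silent zero; a failed log-logistic fit falls back to empirical with a
  warning rather than failing the pixel.
- Pixels whose baseline EVI is invalid or non-positive are flagged and
  excluded from S' rather than producing unstable ratios.
- The sampling variability of the statistical-recovery check is worth
  noting: the median bias of `s_mod_max` against injected truth at noise
   0.02 and 500 pixels is ≈ +0.07 percentage points in expectation with a
  seed-to-seed spread of roughly ±0.15, so single replicates occasionally
  land marginally below zero.

## Known limitations

- PET is an input; no Thornthwaite/Penman computation from temperature.
- No change-point detection for disturbance: the mask is an input.
- CV folds are random, not spatially blocked, so CV statistics on strongly
  autocorrelated landscapes are optimistic (matching common BRT practice).
- NetCDF support is netCDF3 (scipy engine) with a pixel × time layout; no
  reprojection or true 2-D georeferencing.
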