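# Methods

## Problem and modeling frame

`seasdm` implements seasonally-dynamic, sex-stratified presence-only
species distribution modeling for a wide-ranging migratory species, the
setting being continental-scale museum occurrence records of a
migratory tree bat.  Because collections contain presences but no
absences, occupied map pixels are contrasted against a random
*background* sample of available pixels.  The analysis unit is the
1-km² pixel of a planar equal-area grid: multiple records falling in
one pixel count as a single presence *location*.

Records pass two quality filters before modeling: localities
georeferenced only to a state/province or county are removed, as are
records whose estimated georeferencing error exceeds 50 km (a record at
exactly 50 km is kept).  Filtered records are binned by calendar
month–day into four seasons — winter (Dec 1–Feb 29), spring (Mar 1–May
31), summer (Jun 1–Jul 31), autumn (Aug 1–Nov 30) — and stratified by
sex, except in winter where sparse data force pooling, yielding seven
modeling subsets.  Records of unknown sex are included in the pooled
winter subset and excluded (with an audit count) elsewhere; the
sex-specific design leaves no principled home for them.

## Covariates

Each season's candidate covariate set comprises: mean seasonal
temperature (°C, the mean of that season's monthly means), an
adjacent-season mean temperature (prior season for winter/spring/
summer; next season — winter — for autumn), seasonal temperature range
(°C, mean of monthly range values supplied in the climate-normal °C×10
convention and rescaled on ingest), precipitation seasonality (the
coefficient of variation of monthly precipitation, BIO15),
growing-season length (days), and tree cover (%).  Seasonal month sets
mirror the occurrence bins (winter {Dec, Jan, Feb}; summer {Jun, Jul});
using the same bins for response and covariates is an interpretation,
configurable at the stack-construction call.

Before modeling, every covariate pair is screened on a fixed-seed
sample of up to 50,000 jointly unmasked pixels; a pair with |Pearson r|
or |Spearman ρ| > 0.70 loses one member.  The drop choice is
deterministic: variables on a priority list (elevation, mean diurnal
range, raw precipitation totals — the standard casualties in this
covariate family) are dropped first; otherwise the member with the
larger mean absolute correlation to all other candidates goes, with
name order as the final tie-break.  Zero-variance layers have undefined
correlations and are retained but flagged.

Training tables join the subset's occupied pixels (label 1) with
10,000 background pixels drawn uniformly without replacement (the
default; scaled runs use fewer).  A background pixel that coincides
with an occupied pixel appears once, labeled presence.  Background
samples are drawn independently per subset from the subset's seeded
substream.

## The five model forms

All forms expose one contract — fit on the labeled table, predict a
suitability in [0, 1] for any covariate vector — and run under fixed
seeds.  Hyperparameter defaults are community-standard SDM settings,
all overridable per run:

- **GLM** — logistic regression by maximum likelihood with linear and
  quadratic terms per (standardized) covariate; no stepwise selection.
  On separation or divergence (|coefficient| > 30 on the standardized
  scale, or non-convergence) the fit falls back to a ridge-penalized
  solution and flags it.
- **MARS** — additive multivariate adaptive regression splines,
  implemented from scratch: the forward pass greedily adds mirrored
  hinge pairs max(x−t, 0)/max(t−x, 0) with candidate knots at 25
  interior quantiles per covariate, minimizing squared error on the 0/1
  response up to 21 basis columns; the backward pass greedily deletes
  columns to minimize GCV = (RSS/n)/(1 − C/n)² with effective
  parameters C = M + c·(M−1)/2.  The cost-per-knot is c = 4: the
  forward pass searches every candidate knot, and the implied selection
  bias means smaller penalties (c = 2) keep spurious hinges on
  pure-noise covariates about half the time in our seed sweeps, while
  c = 4 prunes noise to the intercept in ≳ 90% of seeds without
  degrading recovery of true hinge knots.  The surviving basis is refit
  as a binomial linear model; prediction passes through the inverse
  logit.
- **BRT** — stochastic gradient boosting (scikit-learn) on binomial
  deviance: depth-3 trees, shrinkage 0.01, bag fraction 0.75, up to
  5,000 trees with internal-validation early stopping (10% holdout,
  patience 20).
- **RF** — random forest of 1,000 fully grown classification trees,
  ⌊√p⌋ split candidates, minimum leaf size 1; suitability is the
  fraction of trees voting presence.
- **Maxent** — the presence-background maximum-entropy model in its
  penalized-logistic formulation: linear, quadratic, and hinge features
  (both orientations, 5 interior-quantile knots per covariate) of the
  standardized covariates, an L1 penalty with multiplier 1.0 (infinite
  shrinkage gives a uniform map), and the fitted linear predictor
  re-centered by the training prevalence so the output logistic
  transform is calibrated at prevalence 0.5.  Feature standardization
  makes suitability *rankings* invariant to affine covariate
  rescaling.

No class weighting is applied: presence and background rows count
equally.

## Evaluation

AUC is rank-based (Mann–Whitney), ties counted one half; it equals the
trapezoidal area under the empirical ROC curve (verified to 1e−12).
Threshold-dependent metrics use the *minimum training presence* (MTP)
threshold — the smallest suitability predicted for any training
presence — with the rule "predicted ≥ threshold ⇒ presence", which
makes training sensitivity exactly 1 by construction.  Cross-validation
is 10-fold, stratified on the label so every fold holds presences; the
MTP threshold is taken from each fold's training partition and
sensitivity/specificity are scored on the held-out fold (whether to
score on held-out or full data was an open choice; held-out is
implemented).  Spatially blocked folds are out of scope.

Variable importance is permutation ΔAUC: baseline AUC minus the mean
AUC over 10 independent shuffles of one covariate column (others
intact), computed per form, averaged across forms, and ranked
descending with name-order tie-breaks.  Ten repeats keep the
Monte-Carlo noise below ~0.01 AUC at the table sizes used.  The
refit-without-variable variant of importance is deliberately not
implemented.

## Ensemble maps and exposure

Each form's continuous surface is binarized at its own MTP threshold;
the ensemble map is the per-pixel mean of the five binary maps, so
unmasked values lie in {0, 0.2, 0.4, 0.6, 0.8, 1.0} (k + 1 levels for k
forms); nodata in any contributor propagates.  Point exposure extracts
the ensemble value of the pixel containing each point (half-open pixel
convention; points outside the grid or on nodata are excluded with an
audit count) and summarizes mean, range, a 10-bin equal-width histogram
on [0, 1] (last bin right-closed), and adjusted Fisher–Pearson
(bias-corrected) sample skewness — negative skew signals points
concentrated in pixels most forms call suitable.

## Synthetic landscapes

The generator exists so the full chain is testable without
multi-gigabyte climate, phenology, and land-cover downloads.
Covariate fields are Gaussian-kernel-smoothed white noise rescaled to a
target mean and SD (smoothing length = autocorrelation length in km;
zero gives white noise), clipped to physical bounds.  The default
scenario derives monthly temperatures from a lapse-rate elevation
term (6.5 °C/km below an 18 °C sea-level baseline), a ±10 °C annual
cycle, and per-season anomaly fields (SD 3.5 °C) that keep
adjacent-season means correlated at roughly 0.5 — below the screening
threshold — while elevation itself correlates with temperature at
≈ −0.85 and is dropped by the screen's priority rule, exercising that
pathway end to end.  Monthly temperature-range layers are emitted in
the °C×10 convention to exercise ingest rescaling.

True suitability is inverse-logit of a linear-plus-quadratic predictor.
The default effects place a growing-season-length optimum near 250 days
with moderate temperature, tree-cover, and temperature-range effects,
and an intercept low enough that prevalence is small (≈ 0.001–0.07 by
season).  This calibration was chosen so that scoring pixels by the
true surface discriminates presences from background at AUC ≈
0.84–0.92 per season — the regime continental presence-only analyses
of wide-ranging vertebrates report — so fitted-model performance on
the scenario is informative rather than saturated.

Presence records are drawn per subset with replacement, pixel
probability proportional to suitability (optionally times an
exponential sampling-bias field), with uniform within-pixel
coordinates, collection dates uniform over the subset's season
(Feb 29 allowed in leap years), the subset's sex (the winter pooled
subset draws from configurable female/unknown fractions, since
collection sex ratios are a free parameter of real data), and
georeferencing errors from a configurable distribution (default
uniform on [0, 25] km, so every generated record passes the QC
filters).  Default subset record counts are
{130, 324, 353, 342, 999, 240, 365} — a realistic seasonal and sex
imbalance with winter scarcity.  Turbine-like point sets are uniform
over the footprint (or proportional to a bias layer); the default
count is 5,000, a scaled-down stand-in for a national turbine
database.  Randomness is organized as a master seed plus stable
per-operation labels, so regenerating one artifact never perturbs
another; occurrence and turbine CSVs are byte-reproducible.

What the generator does **not** emulate: real geography (coastlines,
projections), spatially structured collection effort beyond the single
smooth bias field, temporal trends across the five collection decades,
observer-dependent detectability, and any biotic interactions.  Tests
passing on these landscapes therefore validate the statistical
machinery and its contracts, not the ecological fidelity of any
particular map.

## Numerical and I/O choices

Rasters are exchanged as single-band ESRI ASCII grids (nodata −9999;
NaN in memory); the ASCII format keeps every artifact diffable text.
Planar coordinates are taken from the input when present; otherwise
lon/lat are converted through a sinusoidal equal-area transform —
sufficient because the pipeline only needs area-faithful pixel
assignment, not cartographic accuracy.  Pixels are half-open squares,
lower-left inclusive, everywhere (record rasterization, point
extraction).  Correlations are computed on a 50,000-pixel fixed-seed
sample to bound cost.  Dropping any training row with a nodata
covariate (with an audit count) is the only missing-data policy.

## Scaled problem sizes

Desk-scale runs (tests and the acceptance script) use a 100×100-km
synthetic region, 1,500 background pixels, 2,000 turbines, 250-tree
forests and 1,000-tree boosting caps, and 3 importance repeats in the
factorial run; the model-sanity and importance-recovery checks use the
200×200 single-driver scenario at full specified sizes (300 presences,
2,000 background).  These sizes were chosen so a complete run finishes
in minutes on one CPU while every statistical property under test
remains comfortably measurable.

## Known limitations

- The GLM ridge fallback changes the estimator under separation; the
  flag is recorded in model metadata but not surfaced in metrics
  tables.
- MARS is additive only (`degree=1`); interaction hinges are not
  implemented and requesting them is an error.
- Maxent's L1 path uses a single global penalty multiplier rather than
  per-feature-class regularization schedules.
- The correlation screen's priority list encodes this covariate
  family's conventions; unfamiliar variable sets fall back to the
  mean-absolute-correlation rule, which can drop a scientifically
  preferred variable.
- Background sampling is uniform over available pixels; target-group
  or bias-corrected background schemes are not provided.
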