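# Methods

This note documents the models, the numerical choices and the synthetic data
behind `nichepart`, in the order the pipeline runs them.

## Inclusion rules and adjusted CPUE

Tows with missing depth or bottom temperature are excluded before any model
is fit, so both delta-model stages see the same data. The analysis size range
is the closed interval 30–69 cm fork length (lengths are recorded to the
whole centimeter). Because not all fish in a haul are measured, the haul's
total CPUE is multiplied by the subsample proportion of lengths inside the
range; a haul with positive catch but no measured lengths contributes an
adjusted CPUE of 0 by default (configurable to raise instead). Presence for
the occurrence model is defined on adjusted CPUE — i.e., on the
size-restricted catch — because the downstream overlap indices concern that
size range only.

## The delta-GAM species distribution model

Each species gets a two-stage hurdle model: a binomial GAM with logit link
for presence of the size-restricted catch, and a Gaussian GAM on the natural
log of positive adjusted CPUE. Candidate terms are survey year (categorical
fixed factor), a bivariate smooth of (longitude, latitude), a smooth of depth
and a smooth of bottom temperature.

Smooths are cubic B-splines with quantile-spaced knots and second-order
difference penalties (P-splines); the bivariate term is a tensor product of
marginal bases with an isotropic Kronecker-sum penalty. Each smooth carries a
sum-to-zero constraint so it is identifiable next to the intercept. Basis
dimensions: temperature is fixed at 4 (guards against overfitting a
covariate observed over a narrow range); depth defaults to 10; the spatial
tensor defaults to 6 × 6 marginal bases (35 columns after the constraint).
The temperature cap is part of the model definition; the other two are
generous defaults shrunk by the penalty, and are exposed as estimator
parameters (`k_depth`, `k_lonlat`).

Smoothing parameters minimize generalized cross-validation,
`GCV(λ) = n·D(λ)/(n − edf(λ))²` with D the deviance (RSS for the Gaussian
stage) and `edf` the trace of the influence matrix. The optimizer is
Nelder–Mead over log₁₀ λ (bounds −5..8, best of five common-λ starts); each
evaluation is a penalized IRLS fit for the binomial stage and a single
penalized least-squares solve (with cached cross-products) for the Gaussian
stage. A diagonal jitter of 1e−9 relative scale keeps the Cholesky
factorization stable when a term is shrunk to its null space.

Reported per fit: log-likelihood (profiled MLE scale for the Gaussian
stage), total and per-term effective df, deviance explained, GCV, and
`AIC = −2·logLik + 2·edf` (plus one df for the Gaussian scale). The
all-subsets comparison fits all 16 term subsets, always keeping the
intercept; Akaike weights are normalized over the successful fits and a
failed candidate is recorded as a row, not an exception. Two selection
policies are provided: `min_aic` (the ΔAIC = 0 row) and `force_full` (keep
every candidate term so that predictions stay structurally consistent across
species and response types, the choice the analysis context sometimes
warrants even when a reduced model wins on parsimony).

Predictions: `PO = logit⁻¹(η̂)` and `PA = exp(x̂)`. No lognormal
back-transform bias correction is applied to PA: the standardization step
divides by a per-species statistic of the same field, so any constant factor
`exp(σ²/2)` cancels exactly. Covariates at prediction time are clipped to
the training knot range (cell-mean covariates sit inside the observed range
up to numerical noise). An unseen survey-year level is an error. No spatial
autocorrelation term is included.

The fit engine is implemented in `nichepart.gam` (penalized IRLS + GCV) and
is cross-checked in the test suite against R's mgcv on a shared fixture; the
two agree to r > 0.99 with RMSE a few percent of the response SD.

## Grid, standardization and spatial overlap

A single transverse-Mercator projection (UTM-style: k₀ = 0.9996, 500 km
false easting; zone chosen from the extent centre, configurable) maps the
whole study area to one plane, which is tiled with 100 km × 100 km cells;
membership is half-open `[edge, edge + size)` so edge points resolve
deterministically eastward/northward. The forward/inverse projection uses
the standard USGS series on WGS84; round-trip error is sub-meter, irrelevant
at cell scale. Mean depth and mean temperature over the hauls in each
(year, cell) feed the fitted models at the cell-centre coordinates;
cell-years with no hauls are simply absent.

Per species, `A = PO·PA` is standardized by the species-wide maximum
(mean and median are available; all three give identical cell rankings, the
max keeps values in [0, 1]). Cells whose standardized abundance stays below
0.25 for *both* species in *every* predicted year are excluded — a
whole-cell rule, since the exclusion expresses habitat suitability of the
place, not of a particular year. Spatial overlap is the elementwise product
`S = stdA_a · stdA_b`, and per-cell means average S over the years
available in that cell.

## Diet compositions and dietary overlap

Only non-empty stomachs (fullness code > 1 and at least one prey item) of
fish inside the size range count. A (year, cell) qualifies when both
predators have at least three such stomachs there. Prey-weight proportions
pool weights across the group's stomachs per taxon and normalize by the
group total (the weight-based convention; averaging per-stomach proportions
is the documented alternative behind the pooled default). Schoener's
`D = 1 − ½ Σ|W_a − W_b|` is evaluated over the union of observed taxa at
the raw taxonomic level; folding rare taxa (< 0.01 overall by weight) into
broader groups exists only for display tables and never enters D. Shannon
H′ and Pielou J′ = H′/ln Q use natural logarithms; J′ is undefined (NaN)
for a single-taxon diet. Rarefaction resamples stomachs without replacement;
the curve ends exactly at the observed richness and is checked against the
exact hypergeometric expectation in the tests.

## Partitioning statistics

The ANCOVA treats area (INPFC-style or IPHC-style longitude bands;
configurable breakpoints, half-open intervals) as the fixed factor and
survey year as a *continuous* covariate, with sequential (type-I) sums of
squares, area entered before year; stage one tests the area × year
interaction, stage two the main effects, at α = 0.1. Tukey HSD post hocs
use the studentized range. The partitioning test is the Pearson correlation
of S against D over year-cells having both indices, reported with
t = r√(df/(1−r²)) on df = n − 2 (an identity asserted on every result).
Groups with fewer than 3 pairs or zero variance return an explicitly
undefined result rather than an error.

## The synthetic-data generator

The generator emulates the statistical structure of Gulf-of-Alaska
bottom-trawl and food-habits tables, not their geography in detail:

* Haul locations are uniform in the lon/lat extent (the real survey is
  stratified random; strata enter no downstream formula, so they are not
  simulated). Depth and temperature come from smooth fields; temperature
  additionally carries haul-level Gaussian variability (SD 0.5 °C by
  default) representing local and interannual fluctuation — the catch
  responds to the realized value, the truth surfaces store the mean field.
* Presence is Bernoulli on a logistic linear predictor (year intercept +
  spatial surface + depth response + temperature response); positive CPUE
  is lognormal around a log-scale mean built from the same surfaces with
  stage-specific year intercepts. CPUE > 0 exactly when present.
* The default two-species scenario reproduces the survey's stated
  conditions: ~59% / ~86% of tows positive for the halibut-like and
  arrowtooth-like species, 67.6% / 75.7% of measured fish inside 30–69 cm
  (lognormal lengths, whole-cm records), a 7.7% missing-covariate rate, 13
  survey years (triennial 1990–1999, biennial 2001–2017), ~720 hauls/year,
  up to 200 measured fish per species per haul.
* Stomachs follow the field protocol: up to five per haul, species and
  protocol size bin (< 31, 31–50, 51–70, > 70 cm), with only a fraction of
  haul × species combinations visited (default 0.3 — the real collections
  are sparse). Empty-stomach probabilities default to 0.21 / 0.43 for the
  two predators. A non-empty stomach draws a Dirichlet perturbation of its
  group composition (concentration 30), a 1 + Poisson(2) number of prey
  items with taxa sampled from that perturbed composition, and iid
  lognormal item weights — so the expected pooled composition equals the
  group composition exactly while individual stomachs are sparse and
  variable (giving rarefaction curves their shape). The concentration and
  sampling-sparsity knobs are free parameters: the real between-stomach
  variance is not documented, so they are set to plausible values and not
  calibrated.
* Two diet scenarios ship: `default` (distinct species-typical prey bases,
  size-dependent piscivory for the halibut-like species, an eastern herring
  boost for both) and `partitioning` (near-disjoint diets where spatial
  overlap is high, convergent diets where it is low, producing a built-in
  negative S–D correlation end to end). The default scenario itself shows a
  weak emergent negative S–D coupling because invertebrate-eating small
  size classes dominate where the species co-occur; `simulate_overlap_pairs`
  provides exactly-independent (or exactly-correlated) S–D pairs via a
  Gaussian copula for calibration work.

What passing synthetic tests do **not** show: recovery under the real
survey's stratified, west-to-east seasonally confounded sampling; realistic
bathymetry and coastline geometry; prey taxonomies at the real 59-taxon
resolution; or observation processes such as regurgitation bias. The
pipeline reruns unchanged on real tables supplied in the documented CSV
dialects.

## Problem sizes and determinism

Truth-recovery experiments run at 8 survey years × 2,000 hauls (the scale at
which the occurrence-surface correlation and per-cell overlap correlation
are scored); the AIC-consistency experiment uses 20 replicates of 4 × 500
hauls on the positive-catch stage with a deliberately signal-free
temperature covariate (flat mean field, SD 1.5 °C noise); null calibration
uses 200 replicates of 30 independent S–D pairs. Every stochastic stage
draws from a generator seeded by the scenario or config seed (stage-salted
`SeedSequence`s), so identical configuration yields byte-identical tables.

## Known limitations

* Effective df (and hence AIC) uses the penalized-trace convention; other
  software's df accounting differs by O(1) amounts, so AIC values are
  comparable only within one engine.
* GCV occasionally undersmooths a signal-free covariate, which is why the
  AIC-consistency criterion is a ≥ 70%-of-replicates statement rather than
  a per-replicate one.
* The uncertainty of PO and PA is not propagated into S or D (none is
  propagated in the analysis this package operationalizes).
* Single projection zone for the whole extent: fine for index construction,
  not for survey-grade areal accuracy across a 38°-wide basin.
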