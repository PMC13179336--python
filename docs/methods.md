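# Methods

This note documents the statistical model behind `exposure_triad`, the
synthetic data-generating process used to exercise it, the numerical
conventions, and the design choices that were genuinely open.

## The estimation problem

Household radon tests are reported with postal zips only (addresses are
masked), so both the response and all covariates live at the zone
(ZCTA-like) scale, optionally by calendar month. Three quantities are
estimated per zone z and month m:

* the mean concentration E[X | z, m] (pCi/L),
* the relative variability CoV(z, m) = SD/mean (dimensionless),
* the conditional quantiles Q_q(X | z, m) for q ∈ {0.50, 0.75, 0.90}.

All three use random-forest machinery on a shared zone-month predictor
matrix; concentrations are fit on the log scale, z = ln(x + δ) with
δ = 0.1 pCi/L by default (a measured 0 is admissible after filtering,
and the offset makes the transform total; predictions are reported after
the exact inverse x = exp(z) − δ). The CoV is fit untransformed. All
performance metrics are computed on back-transformed pCi/L.

## Measurement filtering

The cascade removes, in order: (1) durations under 2 or over 15 days
(strict inequalities — exactly 2 or 15 days is retained); (2)
non-residential tests (missing building use counts as non-residential,
the conservative reading of a residential-only criterion); (3) values
below 0 or above 9,999 pCi/L, or records whose test floor is unknown;
(4) values strictly above the 99th percentile of their zip, computed by
linear interpolation on the records entering the step; (5) non-basement
tests; (6) all but the earliest test of each house (later tests are
typically post-mitigation). Ties on the earliest date keep the first
record in stable file order — choosing by value would bias the retained
sample — and are logged. Each step logs removals against the count
entering it, and zip→zone linkage failures (after a fallback table pass)
are logged as a preceding step, so the whole selection is auditable.

A caveat worth recording: the percentile trim is not idempotent on
generic continuous data. With linear-interpolation percentiles and a
strict comparison, the zip maximum always exceeds the interpolated p99
when the top two values are distinct, so re-filtering already-filtered
continuous data can remove one more record per zip. On data with tied
maxima (including the package's hand-enumerable test fixture) the
cascade is exactly idempotent. The trim's reference population (records
surviving steps 1–3, before the basement restriction) is a pinned
convention; reordering steps 4 and 5 changes the per-step counts, which
is regression-tested.

## Features: population-masked areal aggregation

Covariates live on a hexagonal grid (planar axial layout with opaque
cell ids, so a geodesic index such as H3 can substitute without touching
any downstream contract). Cells with zero resident population are masked
before aggregation — an unpopulated hexagon says nothing about
residential exposure — and a zone left with no populated cells is
flagged and excluded. For a zone, each member cell contributes weight
w_c = area_c × (area share of the cell in the zone); population-
proportional weights are available as an option (`weighting:
population`), but masking-plus-area is the default because the protocol
being emulated excludes unpopulated cells rather than weighting by head
count.

Numeric covariates yield a weighted mean (level feature) and a weighted
SD (heterogeneity feature). The SD uses the same weights with no n−1
correction: the member cells are the zone's entire population, not a
sample; a single-cell zone has SD exactly 0. Categorical covariates
yield the weighted modal category (level; ties break to the
lexicographically smallest label) and Shannon entropy in bits,
H = −Σₖ pₖ log₂ pₖ with 0·log 0 ≡ 0 (heterogeneity). Whether pₖ should
be cell counts or area weights is unstated in the protocols this
emulates; area-weighted pₖ is the default (consistent with the other
aggregates) and count-based weights are a one-line option (pass unit
weights). Monthly meteorology aggregates per zone × month and joins onto
the static zone features, producing the zone-month predictor matrix.

Before modelling, numeric features are pruned to one representative per
group of |Pearson r| > 0.85 (transitive closure), keeping the member
most correlated with the target, overridable by an explicit keep-list;
constant columns are excluded with a warning. Pruning exists because
correlated copies dilute permutation importance — a property the test
suite demonstrates directly by duplicating a signal feature.

## The three models

**Average model.** Forest regression of ln(mean + δ) on level features.
Its predictions are also scored against *individual* measurements (each
household test inherits its zone-month prediction) to quantify the
ecological fallacy: zone means are poor proxies for single homes, and
the R² collapse between the two scorings is itself a reported result.

**Relative variability model.** Forest regression of the raw CoV on
heterogeneity features only. Census-style covariates (here, heating
fuel) carry no within-zone variability information in real sources, so
their entropies never enter this model. A zone-month pair whose mean is
0 has an undefined CoV and is dropped with a distinct log reason.

**Individual quantile model.** A quantile regression forest: trees are
grown by scikit-learn's `RandomForestRegressor` (bootstrap resampling;
the library exposes per-tree leaf assignments and in-bag sample indices),
and the conditional-distribution layer is implemented in this package.
For a query x, training sample i receives weight

    w_i(x) = (1/T) Σ_t count_t(i, leaf_t(x)) / |leaf_t(x)|,

where counts are over the bootstrap multiset of tree t (a sample drawn
twice counts twice), and the conditional quantile is the weighted-CDF
inversion inf{y : Σ_i w_i 1[y_i ≤ y] ≥ q}. Weights are nonnegative and
sum to 1 by construction; quantiles are monotone in q because a single
CDF is inverted, so predicted quantiles can never cross. The ensemble
mean prediction equals Σ w_i y_i, which is tested, as is exact (1e−9)
agreement with a deliberately naive double-loop reference implementation
on a grid of small forests.

The phrase "train on the percentiles of individual results" admits two
readings. The implemented default is the standard QRF formulation:
individual measurements are the training responses (each carrying its
zone-month feature row, log-transformed), and quantiles are read from
the conditional CDF, then back-transformed and evaluated against the
empirical zone-month percentiles. The alternative reading — one forest
per quantile regressed directly on the empirical percentiles — is
available via `training_rows="percentiles"` (with non-crossing enforced
by a running maximum, since separate forests do not share a CDF).

Hyperparameter defaults: 500 trees; max features ⌈p/3⌉; minimum leaf 5
for the mean and CoV models and 20 for the quantile model (larger leaves
stabilize tail quantiles); all configurable and recorded in every model
artifact. Missing feature values are median-imputed with an appended
missingness indicator.

## Evaluation protocol

RMSE, R² (1 − SS_res/SS_tot), and MAPE are computed per fold on the
pCi/L scale; rows with a true value of 0 are excluded from MAPE and
counted rather than producing infinities; constant truth makes R²
undefined and is reported as NaN with a reason. Cross-validation is
5-fold with 5 repeats by default, reported as the pooled mean and SD
over all folds × repeats. In the grouped variant, zones are shuffled by
a seeded permutation and dealt round-robin to folds, so no zone ever
appears in both train and test — the honest estimate for prediction on
unseen zones under spatial autocorrelation; a leakage check hard-fails
if a test key is ever seen in training. Permutation importance is the
mean decrease of out-of-sample R² over seeded permutations of one
column, evaluated on held-out data only, with negative values reported
as-is. Note that this quantity is a performance decrease, not a variance
share: permuting the sole feature of a perfect predictor drives the
permuted R² to about −1, so the importance approaches twice the baseline
R². Partial dependence fixes one feature at each grid value and averages
predictions over the observed distribution of the rest; grid points
outside the observed range are flagged as extrapolation. Risk bins are
lower-closed ([0,4), [4,10), [10,20), [20,∞) pCi/L) so that exactly
4.0 pCi/L — the EPA action level — falls in the exceedance bin.

## The synthetic region generator

The generator is the package's test bed and defines the study
conditions. A planar hex grid is partitioned into contiguous zones by
randomized multi-source flood fill. Numeric covariate fields are white
noise smoothed by k = 3 rounds of neighbor averaging (cheap, seedable
spatial autocorrelation; not a full Gaussian-process draw), then
standardized. Categorical covariates are zone-constant with an 8% per-
cell flip probability. A configurable fraction of cells (default 15%)
has zero population; a fraction of boundary cells is split 0.7/0.3
between two zones to exercise area-share weighting; the zip→zone
crosswalk contains a many-zips-to-one-zone case, a zip resolvable only
through the fallback table, and a configurable share of unmatched zips.

Radon is lognormal: per zone and calendar month, ln X ~ Normal(μ_zm,
σ_z) with

    μ_zm = α + Σ_j β_j · z̄_j(zone) + A·cos(2π(m−1)/12),
    σ_z  = exp(γ₀ + Σ_h γ_h · h̃_h(zone)),  clipped to [0.05, 2.5],

where z̄ are standardized population-masked zone covariate means and h̃
standardized zone heterogeneity features (the generator computes these
with its own aggregation code, separate from the analysis-side module,
so parameter recovery is a genuine round trip). The cosine peaks in
January — winter elevation via the stack effect; the functional form is
a modelling choice. A monthly maximum-temperature covariate carries the
same cosine, so models learn seasonality from an observable predictor
rather than the month index. Defaults: α = 1.0 log-pCi/L (median
≈ 2.7 pCi/L, matching the 2.6–2.7 pCi/L medians typical of high-radon
state archives), γ₀ = ln 0.55 (lognormal CoV ≈ 0.6), seasonal amplitude
0.3, β = {permeability 0.5, uranium 0.4, elevation 0.25}, γ =
{elevation SD 0.35, permeability SD 0.30, surface-texture entropy 0.25}.
Nuisance structure: 15% of houses receive 2–3 time-ordered repeat tests
with post-first values damped ×0.5 per step (post-mitigation stand-in);
configurable fractions of records violate each exclusion rule
(durations outside 2–15 days, non-residential use, out-of-range values,
missing floor, non-basement tests — damped ×0.6 since above-basement
levels run lower — and unmatchable zips). Contamination flags are drawn
independently of the radon value, so the filtered sample remains a clean
draw from the stated lognormal (up to the ~1% upper-tail trim).

The exact conditional quantile exp(μ_zm + σ_z Φ⁻¹(q)) is exposed as the
recovery oracle. What the generator does **not** emulate: real geology
or census marginals, measurement-device error, detection-limit
censoring, selection bias in who tests, and fine-scale within-zone
spatial structure below the cell scale. Passing recovery tests therefore
demonstrates that the estimators recover the distribution they target
under the stated sampling process — not that real-world accuracy will
match.

## Problem sizes and reproducibility

Tests and the acceptance script run at desk scale, chosen as the
package's own defaults: the shared small study uses 10 zones × 2 years
with an expected 30 tests per zone-month; recovery experiments use a
30×30-cell, 200-zone region, one year, 36 expected tests per zone-month
(≈10⁵ raw records) with 200-tree forests — about one-third of the
per-zone-month measurement density of a full state archive, which is
orders of magnitude larger and address-restricted. One master seed
drives everything; stage seeds derive from SHA-256 of (master, stage
name), so independent stage re-runs stay reproducible, and the pipeline
manifest records seeds and output hashes.

## Known limitations

* The percentile trim makes the cascade non-idempotent on continuous
  data (see above); counts depend on the pinned step order.
* Back-transformation uses plain exponentiation; a smearing-style bias
  correction is deliberately not applied by default (the convention
  being emulated back-transforms directly), so predicted means on the
  original scale are conditional medians of the lognormal, not means.
* Static features repeat across months in the quantile model; only
  meteorology varies by month.
* Entropy weighting (area vs count) is a convention, not an estimate;
  both are available.
* Grouped CV treats zones as exchangeable groups; it does not model
  distance-based leakage between adjacent zones.
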