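# exposure-triad

Small-area indoor radon exposure surfaces from household test archives:
three complementary forest models that together characterize not just the
**mean** exposure of a zone but also its **within-zone heterogeneity** and
the **full conditional distribution** of individual household values.

Indoor radon (reported in pCi/L of air activity) is the leading cause of
lung cancer in non-smokers, and its concentration varies sharply even
between neighboring houses. State testing archives are address-masked for
privacy, so exposure must be estimated at the postal-zone (ZCTA-like)
scale — where a zone mean alone can badly misrepresent the risk of
individual homes. This package implements, as a tested reusable pipeline:

1. **Average model** — a random forest on the log zone-month mean radon,
   from *level* features (population-masked weighted means and modal
   categories of grid-cell covariates).
2. **Relative variability model** — a random forest on the coefficient
   of variation CoV = σ/μ of radon within a zone-month, from
   *heterogeneity* features (within-zone SDs of numeric covariates and
   Shannon entropies H = −Σₖ pₖ log₂ pₖ of categorical covariates).
3. **Individual quantile model** — a quantile regression forest
   (Meinshausen leaf co-membership weights, implemented in-repo) on
   individual log measurements, predicting arbitrary conditional
   quantiles q₅₀ / q₇₅ / q₉₀, the 90th/50th tail ratio, and risk bins
   (0–4 / 4–10 / 10–20 / 20+ pCi/L; 4 pCi/L is the EPA action level).

Around the models the package provides the measurement **exclusion
cascade** with a per-step audit log (test duration 2–15 days,
residential-only, value range and floor-known, within-zip 99th-percentile
trim, basement-only, first test per house), **zip→zone crosswalk** with
fallback, **population-masked areal aggregation** from a hexagonal grid
to zones, correlated-feature pruning at |r| > 0.85, and the evaluation
protocol: RMSE / R² / MAPE on the back-transformed pCi/L scale under
plain and **zone-grouped** repeated 5-fold cross-validation, permutation
importance (mean decrease of out-of-sample R²), and partial dependence.

Because real statewide radon archives are restricted, the pipeline ships
a first-class **synthetic region generator**: a seeded planar hex grid
with contiguous zones, spatially autocorrelated covariates,
zero-population cells, and lognormal radon with winter-peaking
seasonality (the stack effect) whose log-SD is driven by zone
heterogeneity. Its conditional quantiles exp(μ_zm + σ_z Φ⁻¹(q)) are
available in closed form, so every model can be tested by parameter
recovery against exact ground truth.

> Note on units: 1 pCi/L = 37 Bq/m³. Some sources print the conversion
> as 0.037, which corresponds to Bq/L; this package uses pCi/L
> throughout and does not convert.

## Worked example

```python
from exposure_triad.pipeline import prepare_study
from exposure_triad.synthetic_region import RegionSpec

spec = RegionSpec(n_cells_x=14, n_cells_y=14, n_zones=10, seed=5,
                  n_years=2, tests_per_zone_month=30)
study = prepare_study(spec)
print(study.filter_log.to_table())
print(study.targets.table.head(4).round(3))
```

prints the audit log of the exclusion cascade —

```
step                              removed  remaining
input                                           4362
zip_unmatched                          12       4350
duration_2_to_15_days                  50       4300
residential_only                      225       4075
value_in_range_and_floor_known         49       4026
within_zip_p99_trim                    45       3981
basement_only                         594       3387
first_test_per_house                  496       2891
```

— every rule catches the records the generator contaminated, and 2,891
of 4,362 simulated tests survive — followed by the zone-month targets
all three models share (counts, mean, SD, CoV, empirical percentiles;
pairs with fewer than 10 measurements are excluded):

```
  zone_id  month   n   mean     sd    cov    p50    p75    p90
0   Z0000      1  23  2.165  1.348  0.623  1.735  3.014  4.265
1   Z0000      2  21  2.310  1.178  0.510  2.215  2.762  3.587
2   Z0000      3  21  1.808  1.204  0.666  1.555  2.189  2.950
3   Z0000      4  13  1.399  0.678  0.485  1.487  1.832  2.211
```

Note the January mean (2.17 pCi/L) above the April mean (1.40 pCi/L):
the generator's winter seasonality, which the models learn from the
monthly temperature covariate.

The full pipeline — generate, filter, features, targets, fit all three
models, cross-validate, render choropleths — runs from one config:

```sh
exposure-triad run --config run.yaml
```

with a `run.yaml` as small as

```yaml
out_dir: runs/demo
seed: 11
region: {n_cells_x: 20, n_cells_y: 20, n_zones: 30, n_years: 2}
cv: {k: 5, repeats: 5}
```

The run directory contains `metrics.csv` (RMSE/R²/MAPE × plain vs
grouped CV × model, with SDs across folds), the filter log, feature
provenance and pruning groups, per-zone predictions with tail ratios and
risk bins, permutation importances, partial dependence curves, and maps
(hatched zones = no data). A `manifest.json` records stage seeds and
file hashes; re-running the same config reproduces the deterministic
artifacts hash-identically.

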