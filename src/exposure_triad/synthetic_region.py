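"""Seeded synthetic study region and household radon measurements.

Every downstream stage of the pipeline (filtering, areal aggregation,
target construction, forest models, evaluation) is exercised against data
from this module, which emulates the statistical structure of a state-wide
indoor radon testing program without any external download:

* a planar hexagonal grid of cells carrying population and spatially
  autocorrelated covariates, partitioned into contiguous zones (the
  ZCTA-like prediction unit) with area-share weights;
* right-skewed (lognormal) radon values whose log-mean follows zone-level
  covariates plus a winter-peaking seasonal term (the stack effect), and
  whose log-SD follows zone heterogeneity features, so that within-zone
  dispersion is driven by covariate heterogeneity;
* realistic nuisance structure — zero-population cells, repeat tests per
  house with post-mitigation damping, and a configurable contamination of
  records violating each exclusion rule of the filtering cascade.

The generator's conditional distribution is available in closed form
(:func:`true_conditional_quantile`) so that model recovery can be tested
against exact ground truth.
"""

from __future__ import annotations

import calendar
import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RegionSpec",
    "HexCell",
    "Region",
    "RegionTruth",
    "InvalidSpecError",
    "generate_region",
    "simulate_measurements",
    "simulate_meteorology",
    "true_conditional_quantile",
    "region_digest",
]

NUMERIC_COVARIATES = ("permeability", "elevation", "uranium", "soil_moisture")
CATEGORICAL_COVARIATES: Mapping[str, tuple[str, ...]] = {
    "surface_texture": ("clay", "loam", "sand", "silt"),
    "heating_fuel": ("gas", "oil", "wood", "electric"),
}
UNMATCHED_ZIP = "99999"


class InvalidSpecError(ValueError):
    """Raised when a RegionSpec violates its invariants."""


def _default_beta() -> dict[str, float]:
    return {"permeability": 0.5, "elevation": 0.25, "uranium": 0.4}


def _default_gamma() -> dict[str, float]:
    return {
        "elevation_sd": 0.35,
        "permeability_sd": 0.30,
        "surface_texture_entropy": 0.25,
    }


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of the synthetic region and measurement process.

    ``beta`` maps numeric covariate names to effects on the zone log-mean
    radon (per standard deviation of the zone-level covariate mean);
    ``gamma`` maps heterogeneity feature names (``<numeric>_sd`` or
    ``<categorical>_entropy``) to effects on the zone log-SD.
    ``seasonal_amplitude`` multiplies a cosine peaking in January on the
    log scale.  ``tests_per_zone_month`` is the expected number of tests
    per zone and calendar month pooled across ``n_years``.
    """

    n_cells_x: int = 40
    n_cells_y: int = 40
    n_zones: int = 60
    seed: int = 0
    frac_zero_pop: float = 0.15
    seasonal_amplitude: float = 0.3
    beta: Mapping[str, float] = field(default_factory=_default_beta)
    gamma: Mapping[str, float] = field(default_factory=_default_gamma)
    alpha: float = 1.0
    gamma0: float = float(np.log(0.55))
    n_years: int = 3
    start_year: int = 2015
    tests_per_zone_month: float = 24.0
    smoothing_iterations: int = 3
    frac_split_cells: float = 0.10
    category_flip_prob: float = 0.08
    frac_repeat_houses: float = 0.15
    frac_bad_duration: float = 0.01
    frac_nonresidential: float = 0.05
    frac_out_of_range: float = 0.002
    frac_missing_floor: float = 0.01
    frac_nonbasement: float = 0.15
    frac_unmatched_zip: float = 0.002
    sigma_clip: tuple[float, float] = (0.05, 2.5)

    def validate(self) -> None:
        n_cells = self.n_cells_x * self.n_cells_y
        if self.n_zones < 1 or self.n_zones > n_cells:
            raise InvalidSpecError(
                f"n_zones={self.n_zones} must be in [1, n_cells={n_cells}]"
            )
        fracs = {
            "frac_zero_pop": self.frac_zero_pop,
            "frac_split_cells": self.frac_split_cells,
            "category_flip_prob": self.category_flip_prob,
            "frac_repeat_houses": self.frac_repeat_houses,
            "frac_bad_duration": self.frac_bad_duration,
            "frac_nonresidential": self.frac_nonresidential,
            "frac_out_of_range": self.frac_out_of_range,
            "frac_missing_floor": self.frac_missing_floor,
            "frac_nonbasement": self.frac_nonbasement,
            "frac_unmatched_zip": self.frac_unmatched_zip,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidSpecError(f"{name}={value} must lie in [0, 1]")
        lo, hi = self.sigma_clip
        if lo <= 0 or hi <= lo:
            raise InvalidSpecError(
                f"sigma_clip={self.sigma_clip} requires 0 < low < high"
            )
        if self.n_years < 1:
            raise InvalidSpecError("n_years must be >= 1")
        for key in self.beta:
            if key not in NUMERIC_COVARIATES:
                raise InvalidSpecError(f"beta refers to unknown covariate {key!r}")
        for key in self.gamma:
            base, _, kind = key.rpartition("_")
            ok = (kind == "sd" and base in NUMERIC_COVARIATES) or (
                kind == "entropy" and base in CATEGORICAL_COVARIATES
            )
            if not ok:
                raise InvalidSpecError(f"gamma refers to unknown feature {key!r}")


@dataclass
class HexCell:
    """One grid cell: population, covariates, and zone membership weights."""

    cell_id: str
    center: tuple[float, float]
    area: float
    population: float
    numeric_covariates: dict[str, float]
    categorical_covariates: dict[str, str]
    zone_weights: dict[str, float]


@dataclass
class Region:
    """A generated region: cells, zone ids, and the zip->zone crosswalk."""

    spec: RegionSpec
    cells: list[HexCell]
    zones: list[str]
    crosswalk_primary: pd.DataFrame  # columns: zip, zone_id
    crosswalk_fallback: pd.DataFrame  # columns: zip, zone_id

    def cells_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row: dict = {
                "cell_id": c.cell_id,
                "x": c.center[0],
                "y": c.center[1],
                "area": c.area,
                "population": c.population,
            }
            row.update(c.numeric_covariates)
            row.update(c.categorical_covariates)
            rows.append(row)
        return pd.DataFrame(rows)

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_id": c.cell_id, "zone_id": z, "weight": w}
            for c in self.cells
            for z, w in sorted(c.zone_weights.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class RegionTruth:
    """Exact generative parameters: mu per (zone, month) and sigma per zone."""

    mu: dict[tuple[str, int], float]
    sigma: dict[str, float]
    zone_level: pd.DataFrame  # standardized zone-level covariate means
    zone_het: pd.DataFrame  # standardized zone heterogeneity features


# ---------------------------------------------------------------------------
# grid helpers (odd-r offset hexagonal layout)

_NEIGHBOR_OFFSETS_EVEN = ((1, 0), (-1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1))
_NEIGHBOR_OFFSETS_ODD = ((1, 0), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 1))


def _neighbors(col: int, row: int, nx: int, ny: int):
    offsets = _NEIGHBOR_OFFSETS_ODD if row % 2 else _NEIGHBOR_OFFSETS_EVEN
    for dc, dr in offsets:
        c, r = col + dc, row + dr
        if 0 <= c < nx and 0 <= r < ny:
            yield c, r


def _smooth(field2d: np.ndarray, iterations: int) -> np.ndarray:
    """Iterated neighbor averaging on the hex lattice (cheap autocorrelation)."""
    ny, nx = field2d.shape
    out = field2d.astype(float)
    for _ in range(iterations):
        nxt = np.empty_like(out)
        for r in range(ny):
            for c in range(nx):
                vals = [out[r, c]] + [out[rr, cc] for cc, rr in _neighbors(c, r, nx, ny)]
                nxt[r, c] = float(np.mean(vals))
        out = nxt
    mean, sd = out.mean(), out.std()
    return (out - mean) / sd if sd > 0 else out - mean


def _zone_name(i: int) -> str:
    return f"Z{i:04d}"


def _primary_zip(i: int) -> str:
    return str(15000 + i)


def generate_region(spec: RegionSpec) -> Region:
    """Generate cells, contiguous zones, covariates, and the crosswalk.

    Zone patches are grown by multi-source randomized flood fill so every
    zone is contiguous and the patches partition the grid.  Numeric
    covariates are spatially autocorrelated via iterated neighbor
    averaging of white noise; categorical covariates are patch-constant
    with a per-cell flip probability.  The crosswalk contains one
    many-zips-to-one-zone case (the first zone gets a second zip) and one
    zip present only in the fallback table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny = spec.n_cells_x, spec.n_cells_y
    n_cells = nx * ny

    # --- contiguous zone patches by randomized multi-source flood fill
    zone_of = -np.ones((ny, nx), dtype=int)
    seeds = rng.choice(n_cells, size=spec.n_zones, replace=False)
    frontiers: list[list[tuple[int, int]]] = []
    for z, flat in enumerate(seeds):
        r, c = divmod(int(flat), nx)
        zone_of[r, c] = z
        frontiers.append([(c, r)])
    remaining = n_cells - spec.n_zones
    while remaining > 0:
        order = rng.permutation(spec.n_zones)
        progressed = False
        for z in order:
            frontier = frontiers[z]
            while frontier:
                idx = int(rng.integers(len(frontier)))
                c, r = frontier[idx]
                options = [
                    (cc, rr) for cc, rr in _neighbors(c, r, nx, ny) if zone_of[rr, cc] < 0
                ]
                if not options:
                    frontier[idx] = frontier[-1]
                    frontier.pop()
                    continue
                cc, rr = options[int(rng.integers(len(options)))]
                zone_of[rr, cc] = z
                frontier.append((cc, rr))
                remaining -= 1
                progressed = True
                break
        if not progressed:  # pragma: no cover - flood fill always completes
            raise RuntimeError("flood fill stalled")

    # --- numeric covariate fields
    fields = {
        name: _smooth(rng.normal(size=(ny, nx)), spec.smoothing_iterations)
        for name in NUMERIC_COVARIATES
    }

    # --- categorical fields: zone-constant base + random flips
    cat_fields: dict[str, np.ndarray] = {}
    for name, levels in CATEGORICAL_COVARIATES.items():
        base = rng.integers(len(levels), size=spec.n_zones)
        grid = base[zone_of]
        flip = rng.random(size=(ny, nx)) < spec.category_flip_prob
        grid = np.where(flip, rng.integers(len(levels), size=(ny, nx)), grid)
        cat_fields[name] = grid

    # --- population with a zero-population fraction
    population = np.exp(rng.normal(3.0, 1.0, size=(ny, nx)))
    population = np.where(rng.random(size=(ny, nx)) < spec.frac_zero_pop, 0.0, population)

    zones = [_zone_name(i) for i in range(spec.n_zones)]
    cells: list[HexCell] = []
    dx, dy = 1.0, np.sqrt(3.0) / 2.0
    # split a fraction of boundary cells between two zones (area-share weights)
    split_mask = rng.random(size=(ny, nx)) < spec.frac_split_cells
    for r in range(ny):
        for c in range(nx):
            z = int(zone_of[r, c])
            weights = {zones[z]: 1.0}
            if split_mask[r, c]:
                other = next(
                    (
                        int(zone_of[rr, cc])
                        for cc, rr in _neighbors(c, r, nx, ny)
                        if zone_of[rr, cc] != z
                    ),
                    None,
                )
                if other is not None:
                    weights = {zones[z]: 0.7, zones[other]: 0.3}
            cells.append(
                HexCell(
                    cell_id=f"hx-{r:03d}-{c:03d}",
                    center=(c * dx + 0.5 * dx * (r % 2), r * dy),
                    area=1.0,
                    population=float(population[r, c]),
                    numeric_covariates={k: float(v[r, c]) for k, v in fields.items()},
                    categorical_covariates={
                        k: CATEGORICAL_COVARIATES[k][int(g[r, c])]
                        for k, g in cat_fields.items()
                    },
                    zone_weights=weights,
                )
            )

    # --- crosswalk: every zone a zip; zone 0 has a second zip (many-to-one);
    #     one zip exists only in the fallback table (USPS-update stand-in)
    primary_rows = [{"zip": _primary_zip(i), "zone_id": zones[i]} for i in range(spec.n_zones)]
    primary_rows.append({"zip": "25000", "zone_id": zones[0]})
    fallback_zone = zones[1] if spec.n_zones > 1 else zones[0]
    fallback_rows = [{"zip": "26000", "zone_id": fallback_zone}]
    return Region(
        spec=spec,
        cells=cells,
        zones=zones,
        crosswalk_primary=pd.DataFrame(primary_rows),
        crosswalk_fallback=pd.DataFrame(fallback_rows),
    )


# ---------------------------------------------------------------------------
# zone-level generative parameters

def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    mean = float((weights * values).sum() / wsum)
    var = float((weights * (values - mean) ** 2).sum() / wsum)
    return mean, float(np.sqrt(var))


def _entropy_bits(weights_by_level: Mapping[str, float]) -> float:
    total = sum(weights_by_level.values())
    h = 0.0
    for w in weights_by_level.values():
        p = w / total
        if p > 0:
            h -= p * np.log2(p)
    return float(h)


def _zone_features(region: Region) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-masked zone-level means and heterogeneity features.

    This is the generator's own data-generating aggregation (kept separate
    from the analysis-side spatial_features module so that parameter
    recovery is a genuine round trip, not a tautology).
    """
    spec = region.spec
    level_rows, het_rows = [], []
    for zone in region.zones:
        members = [
            (c, c.zone_weights[zone])
            for c in region.cells
            if zone in c.zone_weights and c.population > 0
        ]
        if not members:
            level_rows.append({"zone_id": zone, **{k: np.nan for k in NUMERIC_COVARIATES}})
            het_rows.append({"zone_id": zone})
            continue
        w = np.array([c.area * share for c, share in members])
        level = {"zone_id": zone}
        het: dict[str, float] = {"zone_id": zone}
        for name in NUMERIC_COVARIATES:
            vals = np.array([c.numeric_covariates[name] for c, _ in members])
            mean, sd = _weighted_mean_sd(vals, w)
            level[name] = mean
            het[f"{name}_sd"] = sd
        for name in CATEGORICAL_COVARIATES:
            counts: dict[str, float] = {}
            for (c, _), wi in zip(members, w):
                lab = c.categorical_covariates[name]
                counts[lab] = counts.get(lab, 0.0) + wi
            het[f"{name}_entropy"] = _entropy_bits(counts)
        level_rows.append(level)
        het_rows.append(het)
    level_df = pd.DataFrame(level_rows).set_index("zone_id")
    het_df = pd.DataFrame(het_rows).set_index("zone_id")

    def standardize(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in out.columns:
            sd = out[col].std(ddof=0)
            out[col] = (out[col] - out[col].mean()) / sd if sd > 0 else 0.0
        return out

    return standardize(level_df), standardize(het_df)


def _truth_from_region(region: Region) -> RegionTruth:
    spec = region.spec
    level, het = _zone_features(region)
    mu: dict[tuple[str, int], float] = {}
    sigma: dict[str, float] = {}
    lo, hi = spec.sigma_clip
    for zone in region.zones:
        mu_z = spec.alpha
        for name, b in spec.beta.items():
            v = level.loc[zone, name]
            mu_z += b * (0.0 if pd.isna(v) else float(v))
        log_sd = spec.gamma0
        for name, g in spec.gamma.items():
            v = het.loc[zone, name] if name in het.columns else 0.0
            log_sd += g * (0.0 if pd.isna(v) else float(v))
        sigma[zone] = float(np.clip(np.exp(log_sd), lo, hi))
        for m in range(1, 13):
            mu[(zone, m)] = mu_z + spec.seasonal_amplitude * np.cos(
                2 * np.pi * (m - 1) / 12.0
            )
    return RegionTruth(mu=mu, sigma=sigma, zone_level=level, zone_het=het)


def true_conditional_quantile(
    truth: RegionTruth, zone: str, month: int, q: float
) -> float:
    """Exact conditional quantile exp(mu_zm + sigma_z * Phi^-1(q)) in pCi/L."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} must lie strictly inside (0, 1)")
    mu = truth.mu[(zone, month)]
    sigma = truth.sigma[zone]
    return float(np.exp(mu + sigma * norm.ppf(q)))


# ---------------------------------------------------------------------------
# measurement simulation

def _zip_for_zone(region: Region, zone_idx: int, rng: np.random.Generator) -> str:
    spec = region.spec
    if zone_idx == 0 and rng.random() < 0.3:
        return "25000"
    if spec.n_zones > 1 and zone_idx == 1 and rng.random() < 0.3:
        return "26000"  # only resolvable through the fallback table
    return _primary_zip(zone_idx)


def simulate_measurements(region: Region) -> tuple[pd.DataFrame, RegionTruth]:
    """Draw household radon tests from the region's generative model.

    Per zone ``z`` and calendar month ``m``, log-radon is
    Normal(mu_zm, sigma_z).  Records carry floor, duration, building use,
    and house id; a configurable fraction of houses receives 2–3
    time-ordered tests with post-first values damped x0.5 (post-mitigation
    stand-in), and configurable fractions violate each exclusion rule of
    the filtering cascade.  Returns the measurement table and the exact
    :class:`RegionTruth`.
    """
    spec = region.spec
    truth = _truth_from_region(region)
    rng = np.random.default_rng(spec.seed + 1)
    rate = spec.tests_per_zone_month / spec.n_years

    rows: list[dict] = []
    house_counter = 0
    for zi, zone in enumerate(region.zones):
        sig = truth.sigma[zone]
        for year in range(spec.start_year, spec.start_year + spec.n_years):
            for month in range(1, 13):
                n = int(rng.poisson(rate))
                if n == 0:
                    continue
                mu = truth.mu[(zone, month)]
                values = np.exp(rng.normal(mu, sig, size=n))
                days_in_month = calendar.monthrange(year, month)[1]
                for v in values:
                    start = date(year, month, int(rng.integers(1, days_in_month + 1)))
                    duration = int(rng.integers(2, 8))
                    house_counter += 1
                    rows.append(
                        {
                            "value": float(v),
                            "zip": _zip_for_zone(region, zi, rng),
                            "floor": "basement",
                            "building_use": "residential",
                            "start_date": start,
                            "end_date": start + timedelta(days=duration),
                            "house_id": f"H{house_counter:07d}",
                            "zone_true": zone,
                        }
                    )

    # repeat tests: damped x0.5 per subsequent test, strictly later dates
    n_base = len(rows)
    repeat_idx = np.flatnonzero(rng.random(n_base) < spec.frac_repeat_houses)
    for i in repeat_idx:
        first = rows[int(i)]
        day_offset = 0
        for k in range(1, int(rng.integers(2, 4))):
            day_offset += int(rng.integers(30, 400))
            start = first["start_date"] + timedelta(days=day_offset)
            duration = int(rng.integers(2, 8))
            rows.append(
                {
                    **first,
                    "value": first["value"] * 0.5**k,
                    "start_date": start,
                    "end_date": start + timedelta(days=duration),
                }
            )

    df = pd.DataFrame(rows)
    n = len(df)

    # contamination masks, independent of the radon value
    bad_dur = rng.random(n) < spec.frac_bad_duration
    short = rng.random(n) < 0.5
    dur = np.where(short, rng.integers(0, 2, size=n), rng.integers(16, 31, size=n))
    for i in np.flatnonzero(bad_dur):
        df.iat[i, df.columns.get_loc("end_date")] = df.iat[
            i, df.columns.get_loc("start_date")
        ] + timedelta(days=int(dur[i]))

    nonres = rng.random(n) < spec.frac_nonresidential
    df.loc[nonres, "building_use"] = "other"

    out_of_range = rng.random(n) < spec.frac_out_of_range
    low_side = rng.random(n) < 0.5
    df.loc[out_of_range & low_side, "value"] = -1.0
    df.loc[out_of_range & ~low_side, "value"] = 10500.0

    missing_floor = rng.random(n) < spec.frac_missing_floor
    df.loc[missing_floor, "floor"] = "missing"
    nonbase = (rng.random(n) < spec.frac_nonbasement) & ~missing_floor
    df.loc[nonbase, "floor"] = rng.choice(["ground", "upper"], size=int(nonbase.sum()))
    # non-basement levels are typically lower; these records are filtered anyway
    df.loc[nonbase, "value"] *= 0.6

    unmatched = rng.random(n) < spec.frac_unmatched_zip
    df.loc[unmatched, "zip"] = UNMATCHED_ZIP

    df = df.sort_values(["start_date", "house_id"], kind="stable").reset_index(drop=True)
    return df, truth


def simulate_meteorology(region: Region) -> pd.DataFrame:
    """Monthly maximum air temperature per cell (the zone x month predictor).

    tmax carries the same cosine seasonality that drives the radon
    log-mean (coldest in January), plus a spatially autocorrelated base
    field tied to elevation and small cell-month noise, so models can
    learn the seasonal term from an observable covariate rather than from
    the month index.
    """
    spec = region.spec
    rng = np.random.default_rng(spec.seed + 2)
    rows = []
    for c in region.cells:
        base = 12.0 - 2.0 * c.numeric_covariates["elevation"]
        for m in range(1, 13):
            seasonal = -8.0 * np.cos(2 * np.pi * (m - 1) / 12.0)
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "month": m,
                    "tmax": base + seasonal + float(rng.normal(0.0, 0.3)),
                }
            )
    return pd.DataFrame(rows)


def region_digest(region: Region, measurements: pd.DataFrame | None = None) -> str:
    """Stable SHA-256 digest of serialized outputs (determinism contract)."""
    h = hashlib.sha256()
    h.update(json.dumps(asdict(region.spec), sort_keys=True, default=str).encode())
    h.update(region.cells_frame().to_csv(index=False).encode())
    h.update(region.membership_frame().to_csv(index=False).encode())
    h.update(region.crosswalk_primary.to_csv(index=False).encode())
    h.update(region.crosswalk_fallback.to_csv(index=False).encode())
    if measurements is not None:
        h.update(measurements.to_csv(index=False).encode())
    return h.hexdigest()
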