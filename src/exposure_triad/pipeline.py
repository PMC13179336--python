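"""End-to-end orchestration: generate -> filter -> features -> targets ->
fit -> evaluate, driven by one validated config and one master seed.

Stage seeds are derived by hashing (master seed, stage name) so any stage
can be re-run independently and reproducibly.  Every run directory gets a
manifest with stage order, seeds, and SHA-256 hashes of written files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import evaluation as ev
from . import forest_models as fm
from . import measurements as ms
from . import plots
from . import spatial_features as sf
from . import synthetic_region as sr
from . import targets as tg

__all__ = [
    "RunConfig",
    "load_config",
    "run_pipeline",
    "Study",
    "prepare_study",
    "level_feature_columns",
    "heterogeneity_feature_columns",
    "cv_average",
    "cv_variability",
    "cv_quantile",
]

# census-style covariates have no within-zone variability information in
# real inputs, so their entropy never enters the variability model
CENSUS_CATEGORICALS = ("heating_fuel",)


# ---------------------------------------------------------------------------
# config schema

class RegionConfig(BaseModel):
    n_cells_x: int = 40
    n_cells_y: int = 40
    n_zones: int = 60
    frac_zero_pop: float = 0.15
    seasonal_amplitude: float = 0.3
    n_years: int = 3
    tests_per_zone_month: float = 24.0


class FilterConfig(BaseModel):
    trim_quantile: float = 0.99


class FeaturesConfig(BaseModel):
    weighting: str = "area"
    prune_threshold: float = 0.85
    keep: list[str] = Field(default_factory=list)


class TargetsConfig(BaseModel):
    min_n: int = 10
    log_offset: float = 0.1
    quantiles: list[float] = Field(default_factory=lambda: [0.5, 0.75, 0.9])


class OneModelConfig(BaseModel):
    n_trees: int = 500
    min_leaf: int = 5


class ModelsConfig(BaseModel):
    average: OneModelConfig = OneModelConfig()
    variability: OneModelConfig = OneModelConfig()
    quantile: OneModelConfig = OneModelConfig(min_leaf=20)


class CVConfig(BaseModel):
    k: int = 5
    repeats: int = 5


class RunConfig(BaseModel):
    out_dir: str
    seed: int = 0
    region: RegionConfig = RegionConfig()
    filter: FilterConfig = FilterConfig()
    features: FeaturesConfig = FeaturesConfig()
    targets: TargetsConfig = TargetsConfig()
    models: ModelsConfig = ModelsConfig()
    cv: CVConfig = CVConfig()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        missing = [" -> ".join(str(p) for p in e["loc"]) for e in err.errors()]
        raise ValueError(f"invalid run config; offending field(s): {missing}") from err


# ---------------------------------------------------------------------------
# in-memory study preparation (shared by the CLI stages, tests, acceptance)

@dataclass
class Study:
    region: sr.Region
    truth: sr.RegionTruth
    raw: pd.DataFrame
    kept: pd.DataFrame
    filter_log: ms.FilterLog
    features: sf.FeatureTable
    targets: tg.ZoneMonthResult
    meteorology: pd.DataFrame = field(repr=False, default=None)

    def model_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(features, targets) aligned on the common (zone, month) index."""
        t = self.targets.table.set_index(["zone_id", "month"]).sort_index()
        common = t.index.intersection(self.features.table.index)
        return self.features.table.loc[common], t.loc[common]


def prepare_study(
    spec: sr.RegionSpec,
    min_n: int = 10,
    weighting: str = "area",
    trim_quantile: float = 0.99,
    quantiles: tuple[float, ...] = (0.5, 0.75, 0.9),
) -> Study:
    """Generate a region, simulate and filter measurements, and build the
    feature and target tables, all in memory."""
    region = sr.generate_region(spec)
    raw, truth = sr.simulate_measurements(region)
    met = sr.simulate_meteorology(region)
    linked, log = ms.crosswalk_zip_to_zone(
        raw, region.crosswalk_primary, region.crosswalk_fallback
    )
    kept, log = ms.apply_exclusions(linked, trim_quantile=trim_quantile, log=log)
    cells = region.cells_frame()
    ft = sf.build_feature_table(
        cells,
        region.membership_frame(),
        numeric_columns=list(sr.NUMERIC_COVARIATES),
        categorical_columns=list(sr.CATEGORICAL_COVARIATES),
        weighting=weighting,
        monthly=met,
    )
    targets = tg.zone_month_stats(kept, min_n=min_n, quantiles=quantiles)
    return Study(region, truth, raw, kept, log, ft, targets, met)


def level_feature_columns(ft: sf.FeatureTable) -> list[str]:
    return ft.columns_by_provenance("level")


def heterogeneity_feature_columns(
    ft: sf.FeatureTable, exclude_census: bool = True
) -> list[str]:
    cols = ft.columns_by_provenance("heterogeneity")
    if exclude_census:
        banned = {f"{c}_entropy" for c in CENSUS_CATEGORICALS}
        cols = [c for c in cols if c not in banned]
    return cols


# ---------------------------------------------------------------------------
# cross-validated model evaluation

def _metrics_vs_individuals(pred_by_key: dict, individuals: pd.DataFrame) -> ev.EvalMetrics:
    keys = list(zip(individuals["zone_id"], individuals["month"]))
    mask = [k in pred_by_key for k in keys]
    sub = individuals.loc[mask]
    preds = np.array([pred_by_key[k] for k, m in zip(keys, mask) if m])
    return ev.compute_metrics(sub["value"].to_numpy(), preds)


def cv_average(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    feature_columns: list[str],
    plan: ev.FoldPlan,
    params: fm.ForestParams,
    log_offset: float = 0.1,
    individuals: pd.DataFrame | None = None,
) -> dict[str, list[ev.EvalMetrics]]:
    """CV of the average model; optionally also score the same zone-level
    predictions against individual measurements (the degradation design)."""

    def fit_score(train, test):
        model = fm.fit_average_model(
            features.loc[train], targets.loc[train], feature_columns, params, log_offset
        )
        pred = model.predict(features.loc[test])
        out = {"average": ev.compute_metrics(targets.loc[test, "mean"].to_numpy(), pred)}
        if individuals is not None:
            pred_by_key = dict(zip(test, pred))
            out["average_vs_individual"] = _metrics_vs_individuals(
                pred_by_key, individuals
            )
        return out

    return ev.cv_evaluate(plan, fit_score)


def cv_variability(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    feature_columns: list[str],
    plan: ev.FoldPlan,
    params: fm.ForestParams,
) -> dict[str, list[ev.EvalMetrics]]:
    def fit_score(train, test):
        model = fm.fit_variability_model(
            features.loc[train], targets.loc[train], feature_columns, params
        )
        pred = model.predict(features.loc[test])
        return {"variability": ev.compute_metrics(targets.loc[test, "cov"].to_numpy(), pred)}

    return ev.cv_evaluate(plan, fit_score)


def cv_quantile(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    measurements: pd.DataFrame,
    feature_columns: list[str],
    plan: ev.FoldPlan,
    params: fm.ForestParams,
    log_offset: float = 0.1,
    quantiles: tuple[float, ...] = (0.5, 0.75, 0.9),
) -> dict[str, list[ev.EvalMetrics]]:
    """CV of the individual QRF: train on the individual measurements of
    training zones-months, score predicted quantiles against the empirical
    zone-month percentiles of the held-out keys."""
    meas = measurements.copy()
    meas["month"] = pd.to_datetime(meas["start_date"]).dt.month
    meas["_key"] = list(zip(meas["zone_id"], meas["month"]))

    def fit_score(train, test):
        train_set = set(train)
        sub = meas.loc[meas["_key"].isin(train_set)]
        model = fm.fit_quantile_model(
            features, sub, feature_columns, params, log_offset, quantiles=quantiles
        )
        pred = model.predict_quantiles(features.loc[test], quantiles)
        out = {}
        for q in quantiles:
            col = f"p{int(round(q * 100)):02d}"
            out[f"quantile_{col}"] = ev.compute_metrics(
                targets.loc[test, col].to_numpy(), pred[float(q)].to_numpy()
            )
        return out

    return ev.cv_evaluate(plan, fit_score)


# ---------------------------------------------------------------------------
# staged pipeline with artifacts

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed, "files": {}}

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.model_dump(), fh)
    with open(out / "config.schema.json", "w") as fh:
        json.dump(RunConfig.model_json_schema(), fh, indent=2)

    def record(stage: str, seed: int, paths: list[Path]) -> None:
        manifest["stages"].append({"stage": stage, "seed": seed})
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    # --- generate + filter + features + targets (in memory, then persisted)
    gen_seed = ev.derive_seed(config.seed, "generate")
    spec = sr.RegionSpec(seed=gen_seed, **config.region.model_dump())
    study = prepare_study(
        spec,
        min_n=config.targets.min_n,
        weighting=config.features.weighting,
        trim_quantile=config.filter.trim_quantile,
        quantiles=tuple(config.targets.quantiles),
    )

    cells_path = out / "cells.csv"
    study.region.cells_frame().to_csv(cells_path, index=False)
    member_path = out / "membership.csv"
    study.region.membership_frame().to_csv(member_path, index=False)
    xwalk_path = out / "crosswalk_primary.csv"
    study.region.crosswalk_primary.to_csv(xwalk_path, index=False)
    xwalk2_path = out / "crosswalk_fallback.csv"
    study.region.crosswalk_fallback.to_csv(xwalk2_path, index=False)
    met_path = out / "meteorology.csv"
    study.meteorology.to_csv(met_path, index=False)
    zones_path = out / "zones.geojson"
    plots.write_zones_geojson(study.region, zones_path)
    record("generate", gen_seed, [cells_path, member_path, xwalk_path, xwalk2_path, met_path, zones_path])

    raw_path = out / "measurements_raw.csv"
    study.raw.to_csv(raw_path, index=False)
    kept_path = out / "measurements_kept.csv"
    study.kept.to_csv(kept_path, index=False)
    log_json = out / "filter_log.json"
    study.filter_log.to_json(log_json)
    log_txt = out / "filter_log.txt"
    log_txt.write_text(study.filter_log.to_table() + "\n")
    record("filter", gen_seed, [raw_path, kept_path, log_json, log_txt])

    features_path = out / "features.csv"
    study.features.table.to_csv(features_path)
    prov_path = out / "feature_provenance.json"
    features_df, targets_df = study.model_frames()

    # correlation pruning against the log mean target, within provenance class
    pruned_level, level_groups = sf.prune_correlated(
        features_df[level_feature_columns(study.features)].select_dtypes("number"),
        pd.Series(np.log(targets_df["mean"] + config.targets.log_offset), index=targets_df.index),
        threshold=config.features.prune_threshold,
        keep=tuple(config.features.keep),
    )
    het_cols_all = heterogeneity_feature_columns(study.features)
    pruned_het, het_groups = sf.prune_correlated(
        features_df[het_cols_all],
        targets_df["cov"],
        threshold=config.features.prune_threshold,
        keep=tuple(config.features.keep),
    )
    mode_cols = [c for c in level_feature_columns(study.features) if c.endswith("_mode")]
    level_cols = pruned_level + mode_cols
    with open(prov_path, "w") as fh:
        json.dump(
            {
                "provenance": study.features.provenance,
                "pruning": {"level": level_groups, "heterogeneity": het_groups},
                "model_features": {
                    "average": level_cols,
                    "variability": pruned_het,
                    "quantile": level_cols + pruned_het,
                },
                "flagged_zones": study.features.flagged_zones,
                "n_masked_cells": study.features.n_masked_cells,
            },
            fh,
            indent=2,
        )
    record("features", gen_seed, [features_path, prov_path])

    targets_path = out / "targets.csv"
    study.targets.table.to_csv(targets_path, index=False)
    excl_path = out / "targets_excluded.json"
    with open(excl_path, "w") as fh:
        json.dump(study.targets.excluded, fh, indent=2)
    record("targets", gen_seed, [targets_path, excl_path])

    # --- fit the three models on all data and persist predictions
    fit_seed = ev.derive_seed(config.seed, "fit")
    qs = tuple(config.targets.quantiles)
    avg_params = fm.ForestParams(
        n_trees=config.models.average.n_trees,
        min_leaf=config.models.average.min_leaf,
        seed=fit_seed,
    )
    var_params = fm.ForestParams(
        n_trees=config.models.variability.n_trees,
        min_leaf=config.models.variability.min_leaf,
        seed=ev.derive_seed(config.seed, "fit-variability"),
    )
    qrf_params = fm.ForestParams(
        n_trees=config.models.quantile.n_trees,
        min_leaf=config.models.quantile.min_leaf,
        seed=ev.derive_seed(config.seed, "fit-quantile"),
    )
    offset = config.targets.log_offset

    avg_model = fm.fit_average_model(features_df, targets_df, level_cols, avg_params, offset)
    var_model = fm.fit_variability_model(features_df, targets_df, pruned_het, var_params)
    kept = study.kept.copy()
    kept["month"] = pd.to_datetime(kept["start_date"]).dt.month
    kept = kept[[k in set(features_df.index) for k in zip(kept["zone_id"], kept["month"])]]
    qrf_model = fm.fit_quantile_model(
        features_df, kept, level_cols + pruned_het, qrf_params, offset, quantiles=qs
    )

    pred = pd.DataFrame(index=targets_df.index)
    pred["predicted_mean"] = avg_model.predict(features_df)
    pred["predicted_cov"] = var_model.predict(features_df)
    qpred = qrf_model.predict_quantiles(features_df, qs)
    for q in qs:
        pred[f"predicted_p{int(round(q * 100)):02d}"] = qpred[float(q)].to_numpy()
    pred["tail_ratio_90_50"] = [
        ev.tail_ratio(h, l) if l > 0 else np.nan
        for h, l in zip(pred["predicted_p90"], pred["predicted_p50"])
    ]
    pred["risk_bin_p50"] = ev.risk_bins(pred["predicted_p50"].clip(lower=0))
    pred_path = out / "predictions.csv"
    pred.to_csv(pred_path)
    for name, model in (("average", avg_model), ("variability", var_model), ("quantile", qrf_model)):
        fm.save_model(model, out / f"model_{name}.joblib")
    record(
        "fit",
        fit_seed,
        [pred_path] + [out / f"model_{n}.joblib" for n in ("average", "variability", "quantile")],
    )

    # --- evaluation: plain and zone-grouped repeated k-fold CV
    eval_seed = ev.derive_seed(config.seed, "evaluate")
    keys = list(targets_df.index)
    groups = {k: k[0] for k in keys}
    plans = {
        "5fold": ev.make_folds(keys, None, config.cv.k, config.cv.repeats, eval_seed),
        "group5fold": ev.make_folds(keys, groups, config.cv.k, config.cv.repeats, eval_seed),
    }
    summaries = []
    for plan_name, plan in plans.items():
        res = cv_average(
            features_df, targets_df, level_cols, plan, avg_params, offset, individuals=kept
        )
        res.update(cv_variability(features_df, targets_df, pruned_het, plan, var_params))
        res.update(
            cv_quantile(
                features_df, targets_df, kept, level_cols + pruned_het, plan,
                qrf_params, offset, qs,
            )
        )
        s = ev.summarize_folds(res)
        s.insert(0, "cv", plan_name)
        summaries.append(s)
    metrics = pd.concat(summaries, ignore_index=True)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics.to_dict(orient="records"), fh, indent=2)

    # permutation importance + PDP for the average model on a held-out split
    rng = np.random.default_rng(eval_seed)
    perm = rng.permutation(len(keys))
    cut = int(0.8 * len(keys))
    tr = [keys[i] for i in perm[:cut]]
    te = [keys[i] for i in perm[cut:]]
    ho_model = fm.fit_average_model(
        features_df.loc[tr], targets_df.loc[tr], level_cols, avg_params, offset
    )
    X_te = features_df.loc[te, level_cols]
    imp = ev.permutation_importance(
        lambda X: ho_model.predict(X),
        X_te,
        targets_df.loc[te, "mean"].to_numpy(),
        n_repeats=10,
        seed=eval_seed,
    )
    imp_path = out / "importance_average.csv"
    imp.to_csv(imp_path, index=False)
    num_imp = [f for f in imp["feature"] if not f.endswith("_mode")]
    pdp_frames = []
    for featname in num_imp[:3]:
        grid = np.linspace(X_te[featname].min(), X_te[featname].max(), 15)
        curve = ev.partial_dependence(lambda X: ho_model.predict(X), X_te, featname, grid)
        curve.insert(0, "feature", featname)
        pdp_frames.append(curve)
    pdp_path = out / "pdp_average.csv"
    pd.concat(pdp_frames, ignore_index=True).to_csv(pdp_path, index=False)

    # maps: January predicted mean and CoV (striped = no data)
    jan = pred.reset_index()
    jan = jan[jan["month"] == 1]
    mean_map = out / "figures" / "predicted_mean_january.png"
    plots.choropleth(
        zones_path,
        dict(zip(jan["zone_id"], jan["predicted_mean"])),
        "Predicted January zone mean radon (pCi/L)",
        mean_map,
    )
    cov_map = out / "figures" / "predicted_cov_january.png"
    plots.choropleth(
        zones_path,
        dict(zip(jan["zone_id"], jan["predicted_cov"])),
        "Predicted January radon CoV",
        cov_map,
        cmap="magma",
        label="CoV",
    )
    imp_fig = out / "figures" / "importance_average.png"
    plots.importance_barplot(imp, "Average model permutation importance", imp_fig)
    record(
        "evaluate",
        eval_seed,
        [metrics_path, out / "metrics.json", imp_path, pdp_path, mean_map, cov_map, imp_fig],
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
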