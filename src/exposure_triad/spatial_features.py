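"""Zone-level predictor matrix from hex-cell covariates.

Cells with zero population are masked before aggregation; numeric
covariates become a weighted zone mean (level feature) and a weighted
zone SD (heterogeneity feature); categorical covariates become the
weighted modal category (level) and Shannon entropy in bits
(heterogeneity).  Weights default to cell area times the cell's
area-share in the zone; population weighting is available as an option.
Highly correlated columns (|r| above a threshold, 0.85 by default) are
pruned to one representative per transitively-closed group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "shannon_entropy",
    "mask_populated",
    "aggregate_numeric",
    "aggregate_categorical",
    "build_feature_table",
    "prune_correlated",
    "FeatureTable",
]


def shannon_entropy(weights) -> float:
    """Shannon entropy H = -sum p_k log2 p_k in bits, with 0*log0 = 0.

    ``weights`` are nonnegative category masses (counts or area weights);
    they are normalized internally.  Total mass must be positive.
    """
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0 or w.sum() <= 0:
        raise ValueError("entropy requires positive total mass")
    if (w < 0).any():
        raise ValueError("entropy weights must be nonnegative")
    p = w / w.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mask_populated(cells: pd.DataFrame, membership: pd.DataFrame):
    """Drop cells with population == 0; flag zones left with no populated cell.

    Returns ``(populated_cells, populated_membership, flagged_zones, n_masked)``.
    Flagged zones must be excluded from downstream modelling.
    """
    populated = cells.loc[cells["population"] > 0].reset_index(drop=True)
    n_masked = len(cells) - len(populated)
    kept_ids = set(populated["cell_id"])
    member = membership.loc[membership["cell_id"].isin(kept_ids)].reset_index(drop=True)
    all_zones = set(membership["zone_id"])
    flagged = sorted(all_zones - set(member["zone_id"]))
    if flagged:
        warnings.warn(
            f"{len(flagged)} zone(s) have no populated cells and are excluded: {flagged}",
            stacklevel=2,
        )
    return populated, member, flagged, n_masked


def aggregate_numeric(values, weights) -> tuple[float, float]:
    """Weighted mean and population-weighted SD over a zone's member cells.

    The SD uses the same weights with no n-1 correction: the member cells
    are the zone's full population, not a sample.  A single-cell zone has
    SD exactly 0.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("aggregate_numeric requires at least one populated cell")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive total")
    mean = float((w * v).sum() / wsum)
    sd = float(np.sqrt((w * (v - mean) ** 2).sum() / wsum))
    return mean, sd


def aggregate_categorical(categories, weights) -> tuple[str, float]:
    """Weighted modal category and Shannon entropy (bits) over member cells.

    Ties on the modal mass break to the lexicographically smallest label.
    """
    cats = list(categories)
    w = np.asarray(weights, dtype=float)
    if not cats:
        raise ValueError("aggregate_categorical requires at least one populated cell")
    masses: dict[str, float] = {}
    for lab, wi in zip(cats, w):
        masses[lab] = masses.get(lab, 0.0) + float(wi)
    mode = min(masses, key=lambda k: (-masses[k], k))
    return mode, shannon_entropy(masses.values())


@dataclass
class FeatureTable:
    """Zone (or zone x month) predictor matrix with column provenance."""

    table: pd.DataFrame
    provenance: dict[str, str]  # column -> "level" | "heterogeneity"
    flagged_zones: list[str] = field(default_factory=list)
    n_masked_cells: int = 0
    pruning_report: list[dict] = field(default_factory=list)

    def columns_by_provenance(self, kind: str) -> list[str]:
        return [c for c, p in self.provenance.items() if p == kind and c in self.table.columns]


def _zone_weights(
    cells: pd.DataFrame, membership: pd.DataFrame, weighting: str
) -> pd.DataFrame:
    merged = membership.merge(cells, on="cell_id", how="inner")
    if weighting == "area":
        merged["w"] = merged["area"] * merged["weight"]
    elif weighting == "population":
        merged["w"] = merged["population"] * merged["weight"]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return merged


def build_feature_table(
    cells: pd.DataFrame,
    membership: pd.DataFrame,
    numeric_columns: list[str],
    categorical_columns: list[str],
    weighting: str = "area",
    monthly: pd.DataFrame | None = None,
    monthly_columns: list[str] | None = None,
) -> FeatureTable:
    """Population-masked areal aggregation of cell covariates to zones.

    Static columns aggregate per zone; ``monthly`` (cell_id, month, value
    columns) aggregates per zone x month and is joined on zone, producing
    a zone x month table.  Without ``monthly`` the table is zone-only.
    """
    populated, member, flagged, n_masked = mask_populated(cells, membership)
    merged = _zone_weights(populated, member, weighting)

    provenance: dict[str, str] = {}
    rows = []
    for zone, grp in merged.groupby("zone_id", sort=True):
        w = grp["w"].to_numpy()
        row: dict = {"zone_id": zone}
        for col in numeric_columns:
            mean, sd = aggregate_numeric(grp[col].to_numpy(), w)
            row[f"{col}_mean"] = mean
            row[f"{col}_sd"] = sd
        for col in categorical_columns:
            mode, ent = aggregate_categorical(grp[col].tolist(), w)
            row[f"{col}_mode"] = mode
            row[f"{col}_entropy"] = ent
        rows.append(row)
    static = pd.DataFrame(rows).set_index("zone_id")
    for col in numeric_columns:
        provenance[f"{col}_mean"] = "level"
        provenance[f"{col}_sd"] = "heterogeneity"
    for col in categorical_columns:
        provenance[f"{col}_mode"] = "level"
        provenance[f"{col}_entropy"] = "heterogeneity"

    if monthly is None:
        return FeatureTable(static, provenance, flagged, n_masked)

    monthly_columns = monthly_columns or [
        c for c in monthly.columns if c not in ("cell_id", "month")
    ]
    pop_monthly = monthly.loc[monthly["cell_id"].isin(set(populated["cell_id"]))]
    mm = member.merge(pop_monthly, on="cell_id", how="inner").merge(
        populated[["cell_id", "area", "population"]], on="cell_id"
    )
    mm["w"] = (
        mm["area"] * mm["weight"] if weighting == "area" else mm["population"] * mm["weight"]
    )
    met_rows = []
    for (zone, month), grp in mm.groupby(["zone_id", "month"], sort=True):
        w = grp["w"].to_numpy()
        row = {"zone_id": zone, "month": int(month)}
        for col in monthly_columns:
            mean, sd = aggregate_numeric(grp[col].to_numpy(), w)
            row[f"{col}_mean"] = mean
            row[f"{col}_sd"] = sd
        met_rows.append(row)
    met = pd.DataFrame(met_rows)
    for col in monthly_columns:
        provenance[f"{col}_mean"] = "level"
        provenance[f"{col}_sd"] = "heterogeneity"
    table = met.merge(static.reset_index(), on="zone_id").set_index(["zone_id", "month"])
    return FeatureTable(table, provenance, flagged, n_masked)


def prune_correlated(
    table: pd.DataFrame,
    target: pd.Series,
    threshold: float = 0.85,
    keep: tuple[str, ...] = (),
) -> tuple[list[str], list[dict]]:
    """Keep one representative per group of |r| > threshold columns.

    Groups are the transitive closure of pairwise |r| > threshold among
    numeric columns (pairwise-complete Pearson correlation).  The retained
    member is the one with the largest |correlation with target|, with
    ties broken lexicographically; an explicit ``keep`` list overrides the
    choice.  Constant columns are excluded before correlation with a
    warning.  Returns ``(kept_columns, groups_report)``.
    """
    numeric = table.select_dtypes(include=[np.number])
    dropped_constant = [
        c for c in numeric.columns if numeric[c].nunique(dropna=True) <= 1
    ]
    if dropped_constant:
        warnings.warn(
            f"constant column(s) excluded before correlation: {dropped_constant}",
            stacklevel=2,
        )
    cols = [c for c in numeric.columns if c not in dropped_constant]
    if not cols:
        return [], []
    corr = numeric[cols].corr().abs()

    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if corr.loc[a, b] > threshold:
                parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for c in cols:
        groups.setdefault(find(c), []).append(c)

    t = pd.to_numeric(target, errors="coerce")
    target_corr = {
        c: abs(numeric[c].corr(t)) if numeric[c].std(ddof=0) > 0 else 0.0 for c in cols
    }
    kept: list[str] = []
    report: list[dict] = []
    for members in groups.values():
        members = sorted(members)
        if len(members) == 1:
            kept.append(members[0])
            continue
        overrides = [c for c in members if c in keep]
        if overrides:
            rep = sorted(overrides)[0]
        else:
            rep = min(
                members,
                key=lambda c: (-np.nan_to_num(target_corr[c]), c),
            )
        kept.append(rep)
        report.append({"members": members, "kept": rep})
    # deterministic output order: original column order
    kept = [c for c in table.columns if c in set(kept)]
    report.sort(key=lambda g: g["members"][0])
    return kept, report
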