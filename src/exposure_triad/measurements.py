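"""Household radon test records: parsing, zip->zone linkage, exclusion cascade.

The cascade mirrors the data-selection protocol of state radon-testing
archives: implausible test durations, non-residential tests, out-of-range
or floor-unknown records, extreme values above the within-zip 99th
percentile, non-basement tests, and repeat tests after the first per house
are removed in that order, with an audit log recording removals per step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "DataError",
    "FilterLog",
    "parse_measurements",
    "crosswalk_zip_to_zone",
    "apply_exclusions",
]

REQUIRED_COLUMNS = (
    "value",
    "zip",
    "floor",
    "building_use",
    "start_date",
    "end_date",
    "house_id",
)

FLOOR_LEVELS = {"basement", "ground", "upper", "missing"}


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class DataError(ValueError):
    """The input data are internally inconsistent (e.g. conflicting crosswalk)."""


@dataclass
class FilterLog:
    """Ordered audit log of the exclusion cascade.

    Each step records ``(step_name, n_removed, n_remaining)``; counts are
    additive, i.e. ``n_remaining`` of a step equals the previous step's
    ``n_remaining`` minus this step's ``n_removed``.
    """

    n_input: int = 0
    steps: list[tuple[str, int, int]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_remaining: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.n_input
        if prev - n_removed != n_remaining:
            raise ValueError(
                f"filter log not additive at {name!r}: {prev} - {n_removed} != {n_remaining}"
            )
        self.steps.append((name, int(n_removed), int(n_remaining)))

    @property
    def n_kept(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_input

    def removals(self) -> tuple[int, ...]:
        return tuple(n for _, n, _ in self.steps)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "steps": [
                {"step": s, "n_removed": r, "n_remaining": k} for s, r, k in self.steps
            ],
            "n_kept": self.n_kept,
            "notes": list(self.notes),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> str:
        width = max([len("input")] + [len(s) for s, _, _ in self.steps]) + 2
        lines = [f"{'step':<{width}}{'removed':>9}{'remaining':>11}"]
        lines.append(f"{'input':<{width}}{'':>9}{self.n_input:>11}")
        for s, r, k in self.steps:
            lines.append(f"{s:<{width}}{r:>9}{k:>11}")
        return "\n".join(lines)


def parse_measurements(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a measurement CSV; return (records, rejects).

    Malformed rows — unparseable dates or values, or ``end_date`` before
    ``start_date`` — are collected into the rejects frame with a
    ``reject_reason`` column rather than silently dropped.
    """
    raw = pd.read_csv(path, dtype={"zip": str, "house_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    df = raw.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["start_date"] = pd.to_datetime(df["start_date"], errors="coerce")
    df["end_date"] = pd.to_datetime(df["end_date"], errors="coerce")
    df["floor"] = df["floor"].fillna("missing").astype(str).str.lower()
    df.loc[~df["floor"].isin(FLOOR_LEVELS), "floor"] = "missing"
    df["building_use"] = df["building_use"].fillna("other").astype(str).str.lower()

    reasons = pd.Series("", index=df.index, dtype=str)
    bad_value = ~np.isfinite(df["value"].to_numpy(dtype=float))
    reasons[bad_value] = "unparseable or non-finite value"
    bad_dates = df["start_date"].isna() | df["end_date"].isna()
    reasons[bad_dates & (reasons == "")] = "unparseable date"
    inverted = (~bad_dates) & (df["end_date"] < df["start_date"])
    reasons[inverted & (reasons == "")] = "end_date before start_date"

    bad = reasons != ""
    rejects = raw.loc[bad].copy()
    rejects["reject_reason"] = reasons[bad]
    return df.loc[~bad].reset_index(drop=True), rejects.reset_index(drop=True)


def _check_crosswalk(table: pd.DataFrame, name: str) -> pd.Series:
    if not {"zip", "zone_id"}.issubset(table.columns):
        raise SchemaError(f"{name} crosswalk needs columns 'zip' and 'zone_id'")
    t = table.astype({"zip": str, "zone_id": str})
    conflicts = t.groupby("zip")["zone_id"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise DataError(
            f"{name} crosswalk maps zip(s) {list(bad.index)} to conflicting zones"
        )
    return t.drop_duplicates("zip").set_index("zip")["zone_id"]


def crosswalk_zip_to_zone(
    measurements: pd.DataFrame,
    primary_table: pd.DataFrame,
    fallback_table: pd.DataFrame | None = None,
    log: FilterLog | None = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """Assign ``zone_id`` by zip: primary table first, then the fallback.

    Records matching neither table are removed and logged as a cascade
    step (``zip_unmatched``), mirroring postal-update fallback linkage.
    """
    primary = _check_crosswalk(primary_table, "primary")
    df = measurements.copy()
    df["zone_id"] = df["zip"].astype(str).map(primary)
    if fallback_table is not None and len(fallback_table):
        fallback = _check_crosswalk(fallback_table, "fallback")
        unmatched = df["zone_id"].isna()
        df.loc[unmatched, "zone_id"] = df.loc[unmatched, "zip"].astype(str).map(fallback)
    if log is None:
        log = FilterLog(n_input=len(df))
    removed = int(df["zone_id"].isna().sum())
    df = df.loc[df["zone_id"].notna()].reset_index(drop=True)
    log.add("zip_unmatched", removed, len(df))
    return df, log


def _p99_by_zip(df: pd.DataFrame, q: float) -> pd.Series:
    # linear-interpolation empirical percentile within each zip
    return df.groupby("zip")["value"].transform(lambda v: np.quantile(v.to_numpy(), q))


def apply_exclusions(
    measurements: pd.DataFrame,
    trim_quantile: float = 0.99,
    log: FilterLog | None = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the six-step exclusion cascade; return (kept, FilterLog).

    Steps, in order, each logged against the count entering that step:

    1. duration fewer than 2 or more than 15 days (strict inequalities;
       exactly 2 or 15 days is retained);
    2. non-residential building use (missing use counts as non-residential);
    3. value < 0 or > 9,999, or test-floor level missing (0 is retained);
    4. value strictly above the within-zip 99th percentile, computed on
       the records entering this step;
    5. floor other than basement;
    6. any test after the house's earliest (ties on start date keep the
       first record in stable file order, logged).
    """
    df = measurements.reset_index(drop=True).copy()
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    if log is None:
        log = FilterLog(n_input=len(df))

    def drop(mask: pd.Series, name: str, current: pd.DataFrame) -> pd.DataFrame:
        removed = int(mask.sum())
        out = current.loc[~mask]
        log.add(name, removed, len(out))
        return out

    duration_days = (df["end_date"] - df["start_date"]).dt.days
    df = drop((duration_days < 2) | (duration_days > 15), "duration_2_to_15_days", df)
    df = drop(df["building_use"] != "residential", "residential_only", df)
    df = drop(
        (df["value"] < 0) | (df["value"] > 9999) | (df["floor"] == "missing"),
        "value_in_range_and_floor_known",
        df,
    )
    if len(df):
        thr = _p99_by_zip(df, trim_quantile)
        df = drop(df["value"] > thr, "within_zip_p99_trim", df)
    else:
        log.add("within_zip_p99_trim", 0, 0)
    df = drop(df["floor"] != "basement", "basement_only", df)

    if len(df):
        order = pd.Series(np.arange(len(df)), index=df.index)
        first_idx = (
            df.assign(_order=order)
            .sort_values(["house_id", "start_date", "_order"], kind="stable")
            .groupby("house_id", sort=False)
            .head(1)
            .index
        )
        ties = (
            df.groupby(["house_id", "start_date"], sort=False).size().gt(1).sum()
        )
        if ties:
            log.notes.append(
                f"{int(ties)} house/date tie(s) at first-test selection; kept stable file order"
            )
        df = drop(~df.index.isin(first_idx), "first_test_per_house", df)
    else:
        log.add("first_test_per_house", 0, 0)

    return df.reset_index(drop=True), log
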