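"""Evaluation protocol: pCi/L-scale metrics, (grouped) repeated k-fold CV,
permutation importance, partial dependence, risk bins, and tail ratios.

Grouped CV assigns every record of a zone to the same fold so that
spatial autocorrelation within zones cannot leak between train and test;
its scores are the honest estimate of performance on unseen zones.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvalMetrics",
    "compute_metrics",
    "FoldPlan",
    "make_folds",
    "cv_evaluate",
    "summarize_folds",
    "permutation_importance",
    "partial_dependence",
    "risk_bins",
    "tail_ratio",
    "derive_seed",
    "RISK_BIN_LABELS",
]

RISK_BIN_LABELS = ("0-4", "4-10", "10-20", "20+")
RISK_BIN_EDGES = (0.0, 4.0, 10.0, 20.0, np.inf)


def derive_seed(master: int, name: str) -> int:
    """Deterministic sub-seed from a master seed and a stage name (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class EvalMetrics:
    """RMSE (pCi/L), R^2, and MAPE (%) on the back-transformed scale."""

    rmse: float
    r2: float
    mape: float
    n: int
    n_mape_excluded: int = 0
    r2_undefined_reason: str | None = None

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "mape": self.mape, "n": self.n}


def compute_metrics(y_true, y_pred) -> EvalMetrics:
    """Single-fold metrics.  Rows with y_true == 0 are excluded from MAPE
    (and counted) instead of producing infinities; a constant y_true makes
    R^2 undefined and is reported as NaN with a reason."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size < 2:
        raise ValueError("compute_metrics requires at least 2 observations")
    resid = p - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2, reason = float("nan"), "constant y_true: total sum of squares is 0"
    else:
        r2, reason = 1.0 - float(np.sum(resid**2)) / ss_tot, None
    nonzero = y != 0
    n_excluded = int((~nonzero).sum())
    mape = float(100.0 * np.mean(np.abs(resid[nonzero] / y[nonzero]))) if nonzero.any() else float("nan")
    return EvalMetrics(rmse, r2, mape, int(y.size), n_excluded, reason)


@dataclass
class FoldPlan:
    """k x repeats train/test key lists; grouped plans never split a group."""

    k: int
    repeats: int
    grouping: str  # "none" | "zone"
    seed: int
    folds: list[dict] = field(default_factory=list)
    # each: {"repeat": r, "fold": f, "train": [...], "test": [...]}

    def validate(self, groups: dict | None = None) -> None:
        for r in range(self.repeats):
            test_union: list = []
            for entry in (e for e in self.folds if e["repeat"] == r):
                train, test = set(entry["train"]), set(entry["test"])
                if train & test:
                    raise ValueError("train/test overlap within a fold")
                if groups is not None and self.grouping != "none":
                    gtrain = {groups[k] for k in train}
                    gtest = {groups[k] for k in test}
                    if gtrain & gtest:
                        raise ValueError("group split between train and test")
                test_union.extend(test)
            if len(test_union) != len(set(test_union)):
                raise ValueError("test sets overlap across folds of one repeat")


def make_folds(keys, groups=None, k: int = 5, repeats: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded (grouped) repeated k-fold plan.

    Groups are shuffled by a seeded permutation and dealt round-robin to
    folds to balance counts; each repeat reshuffles with a derived seed.
    Without ``groups`` each key is its own group (plain k-fold).
    """
    keys = list(keys)
    if groups is None:
        grouping = "none"
        group_of = {key: key for key in keys}
    else:
        grouping = "zone"
        group_of = dict(groups) if not isinstance(groups, dict) else groups
        missing = [key for key in keys if key not in group_of]
        if missing:
            raise KeyError(f"keys without group assignment, e.g. {missing[:5]}")
    unique_groups = sorted({group_of[key] for key in keys}, key=str)
    if len(unique_groups) < k:
        raise ValueError(f"{len(unique_groups)} group(s) < k={k}")
    keys_by_group: dict = {}
    for key in keys:
        keys_by_group.setdefault(group_of[key], []).append(key)

    plan = FoldPlan(k=k, repeats=repeats, grouping=grouping, seed=seed)
    for r in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, f"repeat-{r}"))
        shuffled = [unique_groups[i] for i in rng.permutation(len(unique_groups))]
        for f in range(k):
            test_groups = set(shuffled[f::k])
            test = [key for g in sorted(test_groups, key=str) for key in keys_by_group[g]]
            train = [key for key in keys if group_of[key] not in test_groups]
            plan.folds.append({"repeat": r, "fold": f, "train": train, "test": test})
    plan.validate(group_of)
    return plan


def cv_evaluate(plan: FoldPlan, fit_score) -> dict[str, list[EvalMetrics]]:
    """Run ``fit_score(train_keys, test_keys) -> {name: EvalMetrics}`` over
    every fold of every repeat; hard-fails on train/test key leakage."""
    results: dict[str, list[EvalMetrics]] = {}
    for entry in plan.folds:
        train, test = entry["train"], entry["test"]
        if set(train) & set(test):
            raise RuntimeError("leakage: test key present in training set")
        scores = fit_score(train, test)
        for name, metrics in scores.items():
            results.setdefault(name, []).append(metrics)
    return results


def summarize_folds(results: dict[str, list[EvalMetrics]]) -> pd.DataFrame:
    """Pooled mean and SD of each metric across all folds x repeats."""
    rows = []
    for name, metrics in results.items():
        for stat in ("rmse", "r2", "mape"):
            vals = np.array([getattr(m, stat) for m in metrics], dtype=float)
            rows.append(
                {
                    "model": name,
                    "metric": stat,
                    "mean": float(np.nanmean(vals)),
                    "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n_folds": len(vals),
                }
            )
    return pd.DataFrame(rows)


def permutation_importance(
    predict_fn,
    X_test: pd.DataFrame,
    y_test,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean decrease in out-of-sample R^2 when one column is shuffled.

    ``predict_fn(X) -> predictions`` must be a fitted model evaluated on
    held-out data.  Negative importances are reported as-is.  Returns a
    frame with columns feature, importance, sd, se.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = np.asarray(y_test, dtype=float)
    baseline = compute_metrics(y, predict_fn(X_test)).r2
    rng = np.random.default_rng(seed)
    rows = []
    for col in X_test.columns:
        drops = []
        for _ in range(n_repeats):
            Xp = X_test.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drops.append(baseline - compute_metrics(y, predict_fn(Xp)).r2)
        drops = np.asarray(drops)
        rows.append(
            {
                "feature": col,
                "importance": float(drops.mean()),
                "sd": float(drops.std(ddof=1)) if n_repeats > 1 else 0.0,
                "se": float(drops.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0,
                "baseline_r2": baseline,
            }
        )
    return pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)


def partial_dependence(predict_fn, X: pd.DataFrame, feature: str, grid) -> pd.DataFrame:
    """Mean prediction over the data with ``feature`` pinned to each grid
    value; grid points outside the observed range are flagged."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    lo, hi = X[feature].min(), X[feature].max()
    outside = (grid < lo) | (grid > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} grid point(s) outside observed range of {feature!r}: extrapolation",
            stacklevel=2,
        )
    rows = []
    for g, extra in zip(grid, outside):
        Xg = X.copy()
        Xg[feature] = g
        rows.append(
            {"grid": float(g), "mean_prediction": float(np.mean(predict_fn(Xg))), "extrapolated": bool(extra)}
        )
    return pd.DataFrame(rows)


def risk_bins(values) -> pd.Categorical:
    """Exposure categories [0,4), [4,10), [10,20), [20,inf) pCi/L.

    Lower-closed bins place exactly 4.0 pCi/L (the EPA action level) in
    "4-10", the exceedance convention.  Negative values are a domain error.
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if (v < 0).any():
        raise ValueError("risk_bins requires nonnegative pCi/L values")
    return pd.cut(v, bins=RISK_BIN_EDGES, labels=RISK_BIN_LABELS, right=False, include_lowest=True)


def tail_ratio(q_high: float, q_low: float) -> float:
    """Upper-to-central quantile ratio (e.g. 90th/50th); q_low must be > 0."""
    if q_low <= 0:
        raise ValueError("tail_ratio requires q_low > 0")
    return float(q_high) / float(q_low)
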