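"""The three exposure models and the conditional-distribution machinery.

Tree growing is delegated to scikit-learn's ``RandomForestRegressor``
(which exposes leaf assignments via ``apply`` and bootstrap in-bag
membership via ``estimators_samples_``); everything that defines the
conditional distribution — Meinshausen leaf co-membership weights and the
weighted-CDF quantile inversion — is implemented here.

For a query point x the weight of training sample i is

    w_i(x) = (1/T) * sum_t  count_t(i, leaf_t(x)) / |leaf_t(x)|

where counts are over the bootstrap sample (with multiplicity) of tree t,
and the conditional q-quantile is ``inf{y : sum_i w_i 1[y_i <= y] >= q}``.

Three model wrappers share this machinery:

* **Average model** — forest regression of the log zone-month mean on
  level features (weighted zone means / modal categories).
* **Relative variability model** — forest regression of the raw CoV
  (SD/mean) on heterogeneity features (zone SDs / Shannon entropies).
* **Individual quantile model** — quantile regression forest trained on
  individual log measurements, each carrying its zone-month feature row
  (union of level and heterogeneity features); arbitrary quantiles are
  read off the conditional CDF and back-transformed to pCi/L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .targets import DEFAULT_LOG_OFFSET, back_transform, log_transform

__all__ = [
    "ForestParams",
    "FittedForest",
    "fit_forest",
    "conditional_weights",
    "conditional_quantile",
    "weights_from_leaves",
    "quantiles_from_weights",
    "DesignInfo",
    "fit_design",
    "transform_design",
    "FittedModel",
    "QuantileModel",
    "fit_average_model",
    "fit_variability_model",
    "fit_quantile_model",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.  ``max_features="third"`` means ceil(p/3)."""

    n_trees: int = 500
    max_features: int | float | str = "third"
    min_leaf: int = 5
    seed: int = 0

    def resolve_max_features(self, p: int):
        if self.max_features == "third":
            return max(1, math.ceil(p / 3))
        return self.max_features


class FittedForest:
    """A fitted ensemble plus the leaf/in-bag structures for QRF weights.

    ``trees`` holds, per tree, the bootstrap members sorted by leaf id and
    an index ``leaf -> (start, end)`` into that array, so leaf multisets
    are reconstructible after serialization.
    """

    def __init__(self, model: RandomForestRegressor, X_train: np.ndarray, y_train: np.ndarray, params: ForestParams):
        self.model = model
        self.params = params
        self.X_train = np.asarray(X_train, dtype=float)
        self.y_train = np.asarray(y_train, dtype=float)
        self.n_train = len(self.y_train)
        self._y_order = np.argsort(self.y_train, kind="stable")
        self._y_sorted = self.y_train[self._y_order]
        self.trees: list[tuple[np.ndarray, dict[int, tuple[int, int]]]] = []
        for est, inbag in zip(model.estimators_, model.estimators_samples_):
            train_leaves = est.apply(X_train)
            inbag = np.asarray(inbag)
            leaves = train_leaves[inbag]
            order = np.argsort(leaves, kind="stable")
            members = inbag[order]
            leaves_sorted = leaves[order]
            uniq, starts = np.unique(leaves_sorted, return_index=True)
            bounds = np.append(starts, len(leaves_sorted))
            index = {
                int(leaf): (int(bounds[i]), int(bounds[i + 1]))
                for i, leaf in enumerate(uniq)
            }
            self.trees.append((members, index))

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))

    def _query_weights(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, forest expects {self.model.n_features_in_}"
            )
        query_leaves = np.stack([est.apply(X) for est in self.model.estimators_])
        return weights_from_leaves(self.trees, query_leaves, self.n_train)

    def predict_quantiles(
        self, X: np.ndarray, qs, chunk: int = 256
    ) -> np.ndarray:
        """Conditional quantiles for each row of X; shape (n, len(qs))."""
        qs = _validate_qs(qs)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(qs)))
        for start in range(0, X.shape[0], chunk):
            W = self._query_weights(X[start : start + chunk])
            out[start : start + chunk] = quantiles_from_weights(W, self.y_train, qs)
        return out


def weights_from_leaves(
    trees: list[tuple[np.ndarray, dict[int, tuple[int, int]]]],
    query_leaves: np.ndarray,
    n_train: int,
) -> np.ndarray:
    """Leaf co-membership weights from explicit leaf structures.

    ``trees[t]`` is ``(members, index)``: bootstrap member indices sorted
    by leaf (with multiplicity) and ``leaf -> (start, end)`` slices into
    that array.  ``query_leaves[t, i]`` is the leaf of query i in tree t.
    Each tree spreads mass 1/T uniformly over the bootstrap multiset of
    the query's leaf, so every row sums to 1.
    """
    n_query = query_leaves.shape[1]
    W = np.zeros((n_query, n_train))
    inv_T = 1.0 / len(trees)
    for (members, index), leaves in zip(trees, query_leaves):
        for qi, leaf in enumerate(leaves):
            s, e = index[int(leaf)]
            np.add.at(W[qi], members[s:e], inv_T / (e - s))
    return W


def _validate_qs(qs) -> np.ndarray:
    qs = np.atleast_1d(np.asarray(qs, dtype=float))
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError(f"quantile levels must lie strictly in (0, 1): {qs}")
    return qs


def fit_forest(X, y, params: ForestParams = ForestParams()) -> FittedForest:
    """Fit a bootstrap regression-tree ensemble; deterministic under seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        warnings.warn(
            "constant target: degenerate model, predictions will be constant",
            stacklevel=2,
        )
    model = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=params.resolve_max_features(X.shape[1]),
        min_samples_leaf=params.min_leaf,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return FittedForest(model, X, y, params)


def conditional_weights(forest: FittedForest, X) -> np.ndarray:
    """Normalized training-sample weights for each query row (dense).

    Rows are nonnegative and sum to 1 (to 1e-9): each tree contributes
    total mass 1/T spread over the bootstrap members of the query's leaf.
    """
    return forest._query_weights(X)


def conditional_quantile(weights, y_train, q: float) -> float:
    """inf{y : sum_i w_i 1[y_i <= y] >= q} for a single weight vector."""
    qs = _validate_qs(q)
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    return float(quantiles_from_weights(W, np.asarray(y_train, dtype=float), qs)[0, 0])


_CDF_TOL = 1e-12  # absorbs cumulative-sum roundoff at CDF jump points


def quantiles_from_weights(W: np.ndarray, y_train: np.ndarray, qs) -> np.ndarray:
    """Invert each row's weighted CDF at levels ``qs``; shape (n_rows, len(qs))."""
    qs = _validate_qs(qs)
    order = np.argsort(y_train, kind="stable")
    ys = y_train[order]
    cdf = np.cumsum(W[:, order], axis=1)
    n = len(ys)
    out = np.empty((W.shape[0], len(qs)))
    for j, q in enumerate(qs):
        idx = np.argmax(cdf >= q - _CDF_TOL, axis=1)
        # argmax returns 0 when no entry qualifies (can only happen for
        # q -> 1 with roundoff); clamp to the maximum supported y
        none = cdf[np.arange(W.shape[0]), idx] < q - _CDF_TOL
        idx[none] = n - 1
        out[:, j] = ys[idx]
    return out


# ---------------------------------------------------------------------------
# design-matrix preparation shared by the three models

@dataclass
class DesignInfo:
    """Frozen encoding of a training design: columns, dummies, medians."""

    feature_columns: list[str]
    encoded_columns: list[str]
    medians: dict[str, float]
    indicator_columns: list[str]


def fit_design(df: pd.DataFrame, feature_columns: list[str]) -> tuple[np.ndarray, DesignInfo]:
    """One-hot encode categoricals, median-impute NaNs with indicators."""
    sub = df[feature_columns].copy()
    encoded = pd.get_dummies(sub, dtype=float)
    indicator_cols = []
    medians: dict[str, float] = {}
    for col in encoded.columns:
        if encoded[col].isna().any():
            med = float(encoded[col].median())
            medians[col] = med
            ind = f"{col}__was_missing"
            encoded[ind] = encoded[col].isna().astype(float)
            indicator_cols.append(ind)
            encoded[col] = encoded[col].fillna(med)
    info = DesignInfo(
        feature_columns=list(feature_columns),
        encoded_columns=list(encoded.columns),
        medians=medians,
        indicator_columns=indicator_cols,
    )
    return encoded.to_numpy(dtype=float), info


def transform_design(df: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    sub = df[info.feature_columns].copy()
    encoded = pd.get_dummies(sub, dtype=float)
    for col in info.encoded_columns:
        if col in info.indicator_columns:
            base = col[: -len("__was_missing")]
            encoded[col] = (
                encoded[base].isna().astype(float) if base in encoded else 0.0
            )
    encoded = encoded.reindex(columns=info.encoded_columns, fill_value=0.0)
    for col, med in info.medians.items():
        encoded[col] = encoded[col].fillna(med)
    return encoded.fillna(0.0).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# model wrappers

@dataclass
class FittedModel:
    """Average or relative-variability model artifact."""

    kind: str  # "average" | "variability"
    forest: FittedForest
    design: DesignInfo
    log_scale: bool
    log_offset: float
    params: ForestParams

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = transform_design(features, self.design)
        pred = self.forest.predict_mean(X)
        if self.log_scale:
            pred = back_transform(pred, self.log_offset)
        return pred


@dataclass
class QuantileModel:
    """Individual QRF model artifact (conditional distribution on log scale)."""

    forest: FittedForest
    design: DesignInfo
    log_offset: float
    params: ForestParams
    training_rows: str = "individual"  # or "percentiles" (alternative reading)
    percentile_forests: dict[float, "FittedModel"] = field(default_factory=dict)

    def predict_quantiles(self, features: pd.DataFrame, qs) -> pd.DataFrame:
        qs = _validate_qs(qs)
        if self.training_rows == "percentiles":
            cols = {}
            for q in qs:
                cols[float(q)] = self.percentile_forests[float(q)].predict(features)
            out = pd.DataFrame(cols, index=features.index)
            # enforce non-crossing for the per-quantile-forest variant
            return pd.DataFrame(
                np.maximum.accumulate(out.to_numpy(), axis=1),
                index=out.index,
                columns=out.columns,
            )
        X = transform_design(features, self.design)
        log_q = self.forest.predict_quantiles(X, qs)
        return pd.DataFrame(
            back_transform(log_q, self.log_offset),
            index=features.index,
            columns=[float(q) for q in qs],
        )


def _align(features: pd.DataFrame, target_frame: pd.DataFrame, what: str) -> pd.DataFrame:
    missing = target_frame.index.difference(features.index)
    if len(missing):
        raise KeyError(
            f"{what}: {len(missing)} target key(s) missing from feature table, "
            f"e.g. {list(missing[:5])}"
        )
    return features.loc[target_frame.index]


def fit_average_model(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    feature_columns: list[str],
    params: ForestParams = ForestParams(),
    log_offset: float = DEFAULT_LOG_OFFSET,
) -> FittedModel:
    """Forest on the log zone-month mean from level features.

    ``features`` is indexed by (zone_id, month); ``targets`` carries a
    ``mean`` column on the same index.
    """
    feats = _align(features, targets, "average model")
    X, info = fit_design(feats, feature_columns)
    y = log_transform(targets["mean"].to_numpy(), log_offset)
    forest = fit_forest(X, y, params)
    return FittedModel("average", forest, info, True, log_offset, params)


def fit_variability_model(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    feature_columns: list[str],
    params: ForestParams = ForestParams(),
) -> FittedModel:
    """Forest on the raw CoV from heterogeneity features (no transform)."""
    feats = _align(features, targets, "variability model")
    X, info = fit_design(feats, feature_columns)
    y = targets["cov"].to_numpy(dtype=float)
    forest = fit_forest(X, y, params)
    return FittedModel("variability", forest, info, False, 0.0, params)


def fit_quantile_model(
    features: pd.DataFrame,
    measurements: pd.DataFrame,
    feature_columns: list[str],
    params: ForestParams = ForestParams(min_leaf=20),
    log_offset: float = DEFAULT_LOG_OFFSET,
    training_rows: str = "individual",
    quantiles: tuple[float, ...] = (0.5, 0.75, 0.9),
    targets: pd.DataFrame | None = None,
) -> QuantileModel:
    """Quantile regression forest over individual measurements.

    Each measurement contributes one training row: its zone-month feature
    vector and its log-transformed value.  ``training_rows="percentiles"``
    selects the alternative reading that regresses directly on the
    empirical zone-month percentiles (one forest per quantile).
    """
    if training_rows == "percentiles":
        if targets is None:
            raise ValueError("training_rows='percentiles' requires the targets table")
        feats = _align(features, targets, "quantile model (percentile rows)")
        forests: dict[float, FittedModel] = {}
        X, info = fit_design(feats, feature_columns)
        for i, q in enumerate(quantiles):
            col = f"p{int(round(q * 100)):02d}"
            y = log_transform(targets[col].to_numpy(), log_offset)
            forest = fit_forest(X, y, replace(params, seed=params.seed + i))
            forests[float(q)] = FittedModel("average", forest, info, True, log_offset, params)
        return QuantileModel(
            forest=next(iter(forests.values())).forest,
            design=info,
            log_offset=log_offset,
            params=params,
            training_rows="percentiles",
            percentile_forests=forests,
        )

    keys = pd.MultiIndex.from_frame(
        pd.DataFrame(
            {
                "zone_id": measurements["zone_id"],
                "month": pd.to_datetime(measurements["start_date"]).dt.month,
            }
        )
    )
    missing = keys.unique().difference(features.index)
    if len(missing):
        raise KeyError(
            f"quantile model: {len(missing)} measurement key(s) missing from "
            f"feature table, e.g. {list(missing[:5])}"
        )
    rows = features.loc[keys]
    X, info = fit_design(rows, feature_columns)
    y = log_transform(measurements["value"].to_numpy(), log_offset)
    forest = fit_forest(X, y, params)
    return QuantileModel(forest=forest, design=info, log_offset=log_offset, params=params)


def save_model(model, path) -> None:
    joblib.dump(model, path)


def load_model(path):
    return joblib.load(path)
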