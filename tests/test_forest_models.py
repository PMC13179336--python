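"""Forest fitting, Meinshausen weights, CDF inversion, and the three models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import naive_conditional_weights, naive_quantile
from exposure_triad.forest_models import (
    ForestParams,
    conditional_quantile,
    conditional_weights,
    fit_average_model,
    fit_forest,
    fit_quantile_model,
    fit_variability_model,
    quantiles_from_weights,
    weights_from_leaves,
)


@pytest.fixture(scope="module")
def toy_forest():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(50, 3))
    y = 2.0 * X[:, 0] + rng.normal(size=50) * 0.3
    return fit_forest(X, y, ForestParams(n_trees=12, min_leaf=4, seed=1)), X, y


class TestFitForest:
    def test_constant_target_warns_and_predicts_constant(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.warns(UserWarning, match="constant"):
            forest = fit_forest(X, np.full(20, 3.0), ForestParams(n_trees=5, seed=0))
        assert np.allclose(forest.predict_mean(X), 3.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + rng.normal(size=40) * 0.1
        p1 = fit_forest(X, y, ForestParams(n_trees=10, seed=5)).predict_mean(X)
        p2 = fit_forest(X, y, ForestParams(n_trees=10, seed=5)).predict_mean(X)
        assert np.array_equal(p1, p2)

    def test_single_leaf_tree_predicts_bootstrap_mean(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        forest = fit_forest(X, y, ForestParams(n_trees=1, min_leaf=30, seed=2))
        inbag = np.asarray(forest.model.estimators_samples_[0])
        assert np.allclose(forest.predict_mean(X), y[inbag].mean())


class TestConditionalWeights:
    def test_hand_worked_two_tree_example(self):
        # tree A partitions in-bag samples {0,1}|{2,3}; tree B {0,2}|{1,3};
        # the query lands in {0,1} and {0,2} -> w = (0.5, 0.25, 0.25, 0)
        tree_a = (np.array([0, 1, 2, 3]), {10: (0, 2), 11: (2, 4)})
        tree_b = (np.array([0, 2, 1, 3]), {20: (0, 2), 21: (2, 4)})
        query_leaves = np.array([[10], [20]])
        W = weights_from_leaves([tree_a, tree_b], query_leaves, 4)
        assert np.allclose(W, [[0.5, 0.25, 0.25, 0.0]])

    def test_single_leaf_uniform_weights(self):
        tree = (np.array([5, 6, 7, 8]), {1: (0, 4)})
        W = weights_from_leaves([tree], np.array([[1]]), 10)
        assert np.allclose(W[0, 5:9], 0.25) and W.sum() == pytest.approx(1.0)

    def test_bootstrap_multiplicity_counts(self):
        # sample 2 appears twice in the leaf: it gets double mass
        tree = (np.array([1, 2, 2, 3]), {1: (0, 4)})
        W = weights_from_leaves([tree], np.array([[1]]), 4)
        assert np.allclose(W[0], [0.0, 0.25, 0.5, 0.25])

    def test_weights_sum_to_one_and_match_naive(self, toy_forest):
        forest, X, _ = toy_forest
        queries = X[:8] + 0.05
        W = conditional_weights(forest, queries)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-9)
        assert (W >= 0).all()
        W_naive = naive_conditional_weights(forest, queries)
        assert np.abs(W - W_naive).max() < 1e-9

    def test_feature_count_mismatch_is_shape_error(self, toy_forest):
        forest, _, _ = toy_forest
        with pytest.raises(ValueError, match="features"):
            conditional_weights(forest, np.zeros((1, 5)))

    def test_mean_prediction_equals_weighted_mean(self, toy_forest):
        forest, X, y = toy_forest
        W = conditional_weights(forest, X[:10])
        assert np.allclose(W @ forest.y_train, forest.predict_mean(X[:10]), atol=1e-9)


class TestConditionalQuantile:
    def test_uniform_weights_cdf_inversion(self):
        w = np.full(4, 0.25)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert conditional_quantile(w, y, 0.5) == 2.0
        assert conditional_quantile(w, y, 0.25) == 1.0
        assert conditional_quantile(w, y, 0.26) == 2.0

    def test_upper_tail_returns_max(self):
        rng = np.random.default_rng(1)
        w = rng.dirichlet(np.ones(10))
        y = rng.normal(size=10)
        assert conditional_quantile(w, y, 0.999999) == pytest.approx(y.max())

    def test_matches_naive_cdf_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(3, 30))
            w = rng.dirichlet(np.ones(n))
            y = np.round(rng.normal(size=n), 2)  # ties likely
            for q in (0.1, 0.5, 0.9):
                assert conditional_quantile(w, y, q) == naive_quantile(w, y, q)

    def test_quantiles_never_cross(self, toy_forest):
        forest, X, _ = toy_forest
        rng = np.random.default_rng(3)
        queries = rng.normal(size=(200, 3))
        qs = forest.predict_quantiles(queries, [0.5, 0.75, 0.9])
        assert (np.diff(qs, axis=1) >= 0).all()

    def test_invalid_q_rejected(self, toy_forest):
        forest, X, _ = toy_forest
        for q in (0.0, 1.0, -1.0):
            with pytest.raises(ValueError):
                forest.predict_quantiles(X[:1], [q])


@pytest.fixture(scope="module")
def model_frames(small_study):
    feats, targs = small_study.model_frames()
    from exposure_triad.pipeline import (
        heterogeneity_feature_columns,
        level_feature_columns,
    )

    return {
        "features": feats,
        "targets": targs,
        "level": level_feature_columns(small_study.features),
        "het": heterogeneity_feature_columns(small_study.features),
        "study": small_study,
    }


class TestModelWrappers:
    def test_average_model_strong_signal(self, model_frames):
        """Level features generate the log-mean, so in-sample recovery of
        zone-month means must be strong."""
        m = fit_average_model(
            model_frames["features"], model_frames["targets"], model_frames["level"],
            ForestParams(n_trees=60, seed=0),
        )
        pred = m.predict(model_frames["features"])
        y = model_frames["targets"]["mean"].to_numpy()
        from exposure_triad.evaluation import compute_metrics

        assert compute_metrics(y, pred).r2 > 0.9

    def test_variability_model_output_is_raw_cov(self, model_frames):
        m = fit_variability_model(
            model_frames["features"], model_frames["targets"], model_frames["het"],
            ForestParams(n_trees=40, seed=1),
        )
        pred = m.predict(model_frames["features"])
        assert (pred >= 0).all()
        assert pred.mean() == pytest.approx(
            model_frames["targets"]["cov"].mean(), rel=0.5
        )

    def test_alignment_error_names_missing_keys(self, model_frames):
        bad_targets = model_frames["targets"].copy()
        bad_targets.loc[("Zmissing", 1), :] = np.nan
        with pytest.raises(KeyError, match="Zmissing"):
            fit_average_model(
                model_frames["features"], bad_targets, model_frames["level"],
                ForestParams(n_trees=5, seed=0),
            )

    def test_quantile_model_individual_rows(self, model_frames):
        study = model_frames["study"]
        kept = study.kept.copy()
        kept["month"] = pd.to_datetime(kept["start_date"]).dt.month
        kept = kept[
            [k in set(model_frames["features"].index) for k in zip(kept["zone_id"], kept["month"])]
        ]
        qm = fit_quantile_model(
            model_frames["features"], kept,
            model_frames["level"] + model_frames["het"],
            ForestParams(n_trees=40, min_leaf=20, seed=2),
        )
        pred = qm.predict_quantiles(model_frames["features"], (0.5, 0.75, 0.9))
        assert (pred[0.5] <= pred[0.75]).all() and (pred[0.75] <= pred[0.9]).all()
        # median predictions track empirical medians reasonably in-sample
        emp = model_frames["targets"]["p50"].to_numpy()
        rel = np.abs(pred[0.5].to_numpy() - emp) / emp
        assert np.median(rel) < 0.25

    def test_percentile_rows_alternative_reading(self, model_frames):
        qm = fit_quantile_model(
            model_frames["features"], None,
            model_frames["level"] + model_frames["het"],
            ForestParams(n_trees=20, min_leaf=5, seed=3),
            training_rows="percentiles",
            targets=model_frames["targets"],
        )
        pred = qm.predict_quantiles(model_frames["features"], (0.5, 0.75, 0.9))
        assert (pred[0.5] <= pred[0.9]).all()


def test_recovery_improves_with_more_data():
    """Parameter-recovery error shrinks when the sample grows 4x (seeded)."""
    from exposure_triad.pipeline import (
        heterogeneity_feature_columns,
        level_feature_columns,
        prepare_study,
    )
    from exposure_triad.synthetic_region import RegionSpec, true_conditional_quantile

    errors = {}
    for label, tpm in (("small", 18), ("large", 72)):
        spec = RegionSpec(
            n_cells_x=14, n_cells_y=14, n_zones=12, seed=31, n_years=1,
            tests_per_zone_month=tpm,
        )
        st = prepare_study(spec)
        feats, targs = st.model_frames()
        cols = level_feature_columns(st.features) + heterogeneity_feature_columns(st.features)
        kept = st.kept.copy()
        kept["month"] = pd.to_datetime(kept["start_date"]).dt.month
        kept = kept[[k in set(feats.index) for k in zip(kept["zone_id"], kept["month"])]]
        qm = fit_quantile_model(feats, kept, cols, ForestParams(n_trees=60, min_leaf=10, seed=4))
        pred = qm.predict_quantiles(feats, (0.5,))
        rels = [
            abs(pred.loc[key, 0.5] - true_conditional_quantile(st.truth, key[0], key[1], 0.5))
            / true_conditional_quantile(st.truth, key[0], key[1], 0.5)
            for key in feats.index
        ]
        errors[label] = float(np.median(rels))
    assert errors["large"] < errors["small"]
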