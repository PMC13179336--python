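"""Shared fixtures: the hand-enumerable cascade fixture, a small prepared
study, and a deliberately naive double-loop QRF reference implementation
used as the oracle for the leaf co-membership weight formula."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from exposure_triad.pipeline import Study, prepare_study
from exposure_triad.synthetic_region import RegionSpec


def make_cascade_fixture() -> tuple[pd.DataFrame, dict]:
    """13 hand-written records in one zip: one violation of each cascade
    rule plus one clean repeat-test pair.

    Expected by brute-force enumeration: removals (1, 1, 2, 1, 1, 1) in
    cascade order and 6 kept.  The surviving top value (6.0) is tied so
    the within-zip p99 trim is idempotent on the kept set.
    """

    def rec(rid, value, *, floor="basement", use="residential", start=None,
            duration=3, house=None):
        start = start or date(2015, 3, 1)
        return {
            "record_id": rid,
            "value": value,
            "zip": "15001",
            "zone_id": "Z0001",
            "floor": floor,
            "building_use": use,
            "start_date": pd.Timestamp(start),
            "end_date": pd.Timestamp(start) + pd.Timedelta(days=duration),
            "house_id": house or rid,
        }

    rows = [
        rec("r01", 3.0),
        rec("r02", 4.0, duration=1),            # step 1: duration < 2 days
        rec("r03", 4.0, use="other"),           # step 2: non-residential
        rec("r04", -0.1),                       # step 3: value < 0
        rec("r05", 4.0, floor="missing"),       # step 3: floor unknown
        rec("r06", 500.0),                      # step 4: > within-zip p99
        rec("r07", 3.5, floor="ground"),        # step 5: not a basement test
        rec("r08", 6.0, house="H1", start=date(2015, 1, 5)),
        rec("r09", 2.5, house="H1", start=date(2015, 6, 1)),  # step 6: repeat
        rec("r10", 6.0),
        rec("r11", 4.0),
        rec("r12", 2.0),
        rec("r13", 2.5),
    ]
    expected = {
        "removals": (1, 1, 2, 1, 1, 1),
        "kept_ids": ["r01", "r08", "r10", "r11", "r12", "r13"],
    }
    return pd.DataFrame(rows), expected


@pytest.fixture
def cascade_fixture():
    return make_cascade_fixture()


@pytest.fixture(scope="session")
def small_study() -> Study:
    """A 10-zone, 2-year study reused across modules (seeded, ~4k records)."""
    spec = RegionSpec(
        n_cells_x=14, n_cells_y=14, n_zones=10, seed=5, n_years=2,
        tests_per_zone_month=30,
    )
    return prepare_study(spec)


# ---------------------------------------------------------------------------
# naive QRF reference: double loop over trees and training samples

def naive_conditional_weights(forest, X_query: np.ndarray) -> np.ndarray:
    """Meinshausen weights computed the slow, obvious way."""
    X_query = np.atleast_2d(X_query)
    n = forest.n_train
    T = len(forest.model.estimators_)
    X_train = forest.X_train
    W = np.zeros((X_query.shape[0], n))
    for qi, x in enumerate(X_query):
        for est, inbag in zip(forest.model.estimators_, forest.model.estimators_samples_):
            q_leaf = est.apply(x.reshape(1, -1))[0]
            train_leaves = est.apply(X_train)
            members = [int(i) for i in np.asarray(inbag) if train_leaves[i] == q_leaf]
            if not members:
                continue
            for i in members:
                W[qi, i] += 1.0 / (T * len(members))
    return W


def naive_quantile(weights: np.ndarray, y: np.ndarray, q: float) -> float:
    """inf{y : sum_i w_i 1[y_i <= y] >= q} by scanning sorted distinct y."""
    for val in np.unique(y):
        if weights[y <= val].sum() >= q - 1e-12:
            return float(val)
    return float(np.max(y))
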