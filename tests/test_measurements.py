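"""Parsing, crosswalk linkage, and the exclusion cascade with its audit log."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from exposure_triad.measurements import (
    DataError,
    FilterLog,
    SchemaError,
    apply_exclusions,
    crosswalk_zip_to_zone,
    parse_measurements,
)

HEADER = "value,zip,floor,building_use,start_date,end_date,house_id\n"


def write_csv(tmp_path, body: str, name="m.csv"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestParse:
    def test_well_formed_rows_parse(self, tmp_path):
        path = write_csv(
            tmp_path,
            "2.5,15001,basement,residential,2015-01-01,2015-01-04,h1\n"
            "3.0,15001,ground,residential,2015-02-01,2015-02-04,h2\n"
            "0.0,15002,basement,other,2015-03-01,2015-03-04,h3\n",
        )
        records, rejects = parse_measurements(path)
        assert len(records) == 3 and len(rejects) == 0
        assert records["floor"].tolist() == ["basement", "ground", "basement"]

    def test_inverted_dates_go_to_rejects(self, tmp_path):
        path = write_csv(
            tmp_path,
            "2.5,15001,basement,residential,2015-01-10,2015-01-04,h1\n"
            "3.0,15001,basement,residential,2015-02-01,2015-02-04,h2\n",
        )
        records, rejects = parse_measurements(path)
        assert len(records) == 1
        assert rejects["reject_reason"].tolist() == ["end_date before start_date"]

    def test_unparseable_value_and_date_rejected(self, tmp_path):
        path = write_csv(
            tmp_path,
            "oops,15001,basement,residential,2015-01-01,2015-01-04,h1\n"
            "3.0,15001,basement,residential,not-a-date,2015-02-04,h2\n",
        )
        records, rejects = parse_measurements(path)
        assert len(records) == 0 and len(rejects) == 2

    def test_empty_file_with_header(self, tmp_path):
        records, rejects = parse_measurements(write_csv(tmp_path, ""))
        assert len(records) == 0 and len(rejects) == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("value,zip,floor,start_date,end_date,house_id\n")
        with pytest.raises(SchemaError, match="building_use"):
            parse_measurements(path)


class TestCrosswalk:
    @pytest.fixture
    def tables(self):
        primary = pd.DataFrame({"zip": ["11111", "22222"], "zone_id": ["A", "B"]})
        fallback = pd.DataFrame({"zip": ["33333"], "zone_id": ["C"]})
        return primary, fallback

    def make(self, zips):
        return pd.DataFrame(
            {
                "value": 1.0,
                "zip": zips,
                "floor": "basement",
                "building_use": "residential",
                "start_date": pd.Timestamp("2015-01-01"),
                "end_date": pd.Timestamp("2015-01-04"),
                "house_id": [f"h{i}" for i in range(len(zips))],
            }
        )

    def test_primary_then_fallback_then_removed(self, tables):
        primary, fallback = tables
        linked, log = crosswalk_zip_to_zone(
            self.make(["11111", "33333", "44444"]), primary, fallback
        )
        assert linked["zone_id"].tolist() == ["A", "C"]
        assert log.steps == [("zip_unmatched", 1, 2)]

    def test_conflicting_crosswalk_is_a_data_error(self, tables):
        _, fallback = tables
        conflicted = pd.DataFrame({"zip": ["11111", "11111"], "zone_id": ["A", "B"]})
        with pytest.raises(DataError, match="11111"):
            crosswalk_zip_to_zone(self.make(["11111"]), conflicted, fallback)


class TestCascade:
    def test_fixture_counts_match_hand_enumeration(self, cascade_fixture):
        df, expected = cascade_fixture
        kept, log = apply_exclusions(df)
        assert log.removals() == expected["removals"]
        assert kept["record_id"].tolist() == expected["kept_ids"]
        assert log.n_kept == len(expected["kept_ids"])

    def test_fixture_counts_match_brute_force(self, cascade_fixture):
        """Independent brute-force cascade on plain Python rows."""
        df, _ = cascade_fixture
        rows = df.to_dict(orient="records")
        surv = [r for r in rows if 2 <= (r["end_date"] - r["start_date"]).days <= 15]
        n1 = len(rows) - len(surv)
        surv = [r for r in surv if r["building_use"] == "residential"]
        surv2 = [
            r for r in surv if 0 <= r["value"] <= 9999 and r["floor"] != "missing"
        ]
        n3 = len(surv) - len(surv2)
        vals = sorted(r["value"] for r in surv2)  # single zip in the fixture
        p99 = float(np.quantile(vals, 0.99))
        surv3 = [r for r in surv2 if r["value"] <= p99]
        surv4 = [r for r in surv3 if r["floor"] == "basement"]
        first = {}
        for r in surv4:
            key = r["house_id"]
            if key not in first or r["start_date"] < first[key]["start_date"]:
                first[key] = r
        surv5 = [r for r in surv4 if first[r["house_id"]] is r]
        kept, log = apply_exclusions(df)
        assert log.removals() == (
            n1, 1, n3, len(surv2) - len(surv3), len(surv3) - len(surv4),
            len(surv4) - len(surv5),
        )
        assert kept["record_id"].tolist() == [r["record_id"] for r in surv5]

    def test_cascade_is_idempotent_on_its_output(self, cascade_fixture):
        df, _ = cascade_fixture
        kept, _ = apply_exclusions(df)
        kept2, log2 = apply_exclusions(kept)
        assert log2.removals() == (0, 0, 0, 0, 0, 0)
        assert kept2["record_id"].tolist() == kept["record_id"].tolist()

    def test_sum_of_removals_plus_kept_equals_input(self, cascade_fixture):
        df, _ = cascade_fixture
        kept, log = apply_exclusions(df)
        assert sum(log.removals()) + len(kept) == len(df)

    @pytest.mark.parametrize(
        "duration,kept_expected",
        [(1, False), (2, True), (15, True), (16, False)],
    )
    def test_duration_boundaries_are_strict(self, duration, kept_expected):
        start = pd.Timestamp("2015-01-01")
        df = pd.DataFrame(
            [
                {
                    "value": 2.0,
                    "zip": "15001",
                    "floor": "basement",
                    "building_use": "residential",
                    "start_date": start,
                    "end_date": start + pd.Timedelta(days=duration),
                    "house_id": "h1",
                }
            ]
        )
        kept, _ = apply_exclusions(df)
        assert (len(kept) == 1) is kept_expected

    @pytest.mark.parametrize("value,kept_expected", [(0.0, True), (-0.1, False), (9999.0, True), (9999.5, False)])
    def test_value_boundaries(self, value, kept_expected):
        start = pd.Timestamp("2015-01-01")
        df = pd.DataFrame(
            [
                {
                    "value": value,
                    "zip": "15001",
                    "floor": "basement",
                    "building_use": "residential",
                    "start_date": start,
                    "end_date": start + pd.Timedelta(days=3),
                    "house_id": "h1",
                }
            ]
        )
        kept, _ = apply_exclusions(df)
        assert (len(kept) == 1) is kept_expected

    def test_step_order_p99_before_basement_is_pinned(self):
        """A ground-floor zip maximum is trimmed at step 4 in cascade order;
        swapping steps 4 and 5 would shift removals between the two steps."""
        start = pd.Timestamp("2015-01-01")

        def rec(rid, value, floor):
            return {
                "record_id": rid, "value": value, "zip": "15001",
                "floor": floor, "building_use": "residential",
                "start_date": start, "end_date": start + pd.Timedelta(days=3),
                "house_id": rid,
            }

        rows = [rec("a", 600.0, "ground"), rec("b", 500.0, "basement")] + [
            rec(f"c{i}", v, "basement") for i, v in enumerate([2, 3, 3, 4, 5, 6, 6])
        ]
        df = pd.DataFrame(rows)
        kept, log = apply_exclusions(df)
        by_name = {name: n for name, n, _ in log.steps}
        # narrative order: the trim removes the ground-floor 600 (zip max),
        # then the basement step has nothing left to remove
        assert by_name["within_zip_p99_trim"] == 1
        assert by_name["basement_only"] == 0
        assert "b" in kept["record_id"].tolist()

    def test_first_test_tie_keeps_stable_order_and_logs(self):
        start = pd.Timestamp("2015-01-01")
        df = pd.DataFrame(
            [
                {
                    "record_id": rid, "value": v, "zip": "15001",
                    "floor": "basement", "building_use": "residential",
                    "start_date": start, "end_date": start + pd.Timedelta(days=3),
                    "house_id": "same-house",
                }
                for rid, v in [("first", 5.0), ("second", 5.0)]
            ]
        )
        kept, log = apply_exclusions(df)
        assert kept["record_id"].tolist() == ["first"]
        assert any("tie" in note for note in log.notes)

    def test_empty_input_yields_zero_log(self):
        df = pd.DataFrame(
            columns=["value", "zip", "floor", "building_use", "start_date", "end_date", "house_id"]
        )
        df["start_date"] = pd.to_datetime(df["start_date"])
        df["end_date"] = pd.to_datetime(df["end_date"])
        kept, log = apply_exclusions(df)
        assert len(kept) == 0 and log.removals() == (0, 0, 0, 0, 0, 0)

    def test_filter_log_additivity_enforced(self):
        log = FilterLog(n_input=10)
        log.add("a", 3, 7)
        with pytest.raises(ValueError):
            log.add("b", 2, 6)


def test_clean_generator_only_trims_extremes(small_study_clean):
    """With all contamination fractions at 0, every cascade step except the
    within-zip p99 trim removes nothing; the trim removes at most ~1%."""
    log = small_study_clean["log"]
    by_name = {name: n for name, n, _ in log.steps}
    for step in (
        "zip_unmatched", "duration_2_to_15_days", "residential_only",
        "value_in_range_and_floor_known", "basement_only", "first_test_per_house",
    ):
        assert by_name[step] == 0
    assert by_name["within_zip_p99_trim"] <= 0.02 * log.n_input


@pytest.fixture(scope="module")
def small_study_clean():
    from exposure_triad.measurements import apply_exclusions, crosswalk_zip_to_zone
    from exposure_triad.synthetic_region import RegionSpec, generate_region, simulate_measurements

    spec = RegionSpec(
        n_cells_x=10, n_cells_y=10, n_zones=6, seed=17, n_years=1,
        tests_per_zone_month=40, frac_repeat_houses=0.0, frac_bad_duration=0.0,
        frac_nonresidential=0.0, frac_out_of_range=0.0, frac_missing_floor=0.0,
        frac_nonbasement=0.0, frac_unmatched_zip=0.0,
    )
    region = generate_region(spec)
    meas, _ = simulate_measurements(region)
    linked, log = crosswalk_zip_to_zone(meas, region.crosswalk_primary, region.crosswalk_fallback)
    kept, log = apply_exclusions(linked, log=log)
    return {"kept": kept, "log": log}
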