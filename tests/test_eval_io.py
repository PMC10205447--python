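"""Evaluation metrics and published-table serialization."""

import math

import pandas as pd
import pytest

from mobisynth import eval_io
from mobisynth.errors import DataError, ValidationError


def js_oracle(p, q):
    """Closed-form sqrt(1/2 KL(p||m) + 1/2 KL(q||m)), base-2 logs."""
    m = [(a + b) / 2 for a, b in zip(p, q)]
    def kl(a, b):
        return sum(x * math.log2(x / y) for x, y in zip(a, b) if x > 0)
    return math.sqrt(0.5 * kl(p, m) + 0.5 * kl(q, m))


class TestJsDistance:
    def test_identity_is_zero(self):
        assert eval_io.js_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_supports_give_one(self):
        assert eval_io.js_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("p,q", [
        ([1.0, 0.0], [0.5, 0.5]),
        ([0.2, 0.3, 0.5], [0.5, 0.25, 0.25]),
        ([0.1, 0.1, 0.8, 0.0], [0.25, 0.25, 0.25, 0.25]),
    ])
    def test_matches_closed_form_oracle(self, p, q):
        assert eval_io.js_distance(p, q) == pytest.approx(js_oracle(p, q), abs=1e-12)

    def test_symmetry(self):
        p, q = [0.2, 0.8], [0.6, 0.4]
        assert eval_io.js_distance(p, q) == pytest.approx(eval_io.js_distance(q, p))

    def test_bad_normalisation_rejected(self):
        with pytest.raises(DataError):
            eval_io.js_distance([0.5, 0.6], [0.5, 0.5])

    def test_negative_entries_rejected(self):
        with pytest.raises(DataError):
            eval_io.js_distance([-0.5, 1.5], [0.5, 0.5])


class TestMarginalReport:
    def _margins(self):
        return pd.DataFrame({
            "zone_id": ["Z1"] * 2 + ["Z2"] * 2,
            "gender": ["Male", "Female"] * 2,
            "age_group": ["30-34"] * 4,
            "count": [50, 50, 100, 100],
        })

    def _persons(self, z1m=50, z1f=50, z2m=100, z2f=100):
        rows = []
        for zone, gender, n in (("Z1", "Male", z1m), ("Z1", "Female", z1f),
                                ("Z2", "Male", z2m), ("Z2", "Female", z2f)):
            rows += [{"zone_id": zone, "gender": gender, "age_group": "30-34"}] * n
        return pd.DataFrame(rows)

    def test_exact_match_gives_all_zero(self):
        report = eval_io.marginal_diff_report(self._persons(), self._margins())
        assert (report["pct_diff"] == 0).all()
        summary = eval_io.marginal_summary(report)
        assert (summary["share_within_0.5pct"] == 1.0).all()

    def test_single_unit_deficit_is_minus_one_percent(self):
        report = eval_io.marginal_diff_report(self._persons(z2m=99), self._margins())
        row = report[(report.zone_id == "Z2") & (report.category == "Male")]
        assert row["pct_diff"].iloc[0] == pytest.approx(-1.0)

    def test_one_row_per_zone_attribute_category(self):
        report = eval_io.marginal_diff_report(self._persons(), self._margins())
        ok = report[report["status"] == "ok"]
        assert len(ok) == 2 * (2 + 1)  # 2 zones x (2 genders + 1 age group)
        assert not ok.duplicated(["zone_id", "attribute", "category"]).any()

    def test_missing_zone_reported_not_raised(self):
        persons = self._persons()
        report = eval_io.marginal_diff_report(
            persons[persons.zone_id == "Z1"], self._margins())
        assert (report.loc[report.zone_id == "Z2", "status"] == "missing").all()


class TestTableRoundTrips:
    def _persons(self):
        return pd.DataFrame({
            "PId": [1, 2, 3], "HId": [1, 1, 2],
            "gender": ["Male", "Female", "Female"], "age": [34, 31, 7],
            "marital_status": ["couple", "couple", "age<18"],
            "employment": [1, 0, 0], "studenthood": [0, 1, 1],
            "income_class": ["Upper-middle", "Low", "No"],
            "n_cars": [1, 0, 0], "zone_id": ["Z1", "Z1", "Z1"],
            "municipality_id": ["M1", "M1", "M1"]})

    def test_person_table_round_trip(self, tmp_path):
        path = tmp_path / "p.csv"
        eval_io.write_person_table(self._persons(), path)
        back = eval_io.read_person_table(path)
        pd.testing.assert_frame_equal(back, self._persons())

    def test_person_table_snake_case_round_trip(self, tmp_path):
        path = tmp_path / "p.csv"
        eval_io.write_person_table(self._persons(), path, snake_case=True)
        assert "marital_status" in path.read_text().splitlines()[0]
        pd.testing.assert_frame_equal(eval_io.read_person_table(path),
                                      self._persons())

    def test_household_example_row_parses(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("HId,Type,Size,Number of children,Number of cars\n"
                        "1,couple,2,0,0\n")
        hh = eval_io.read_household_table(path)
        assert hh.iloc[0].to_dict() == {"HId": 1, "type": "couple", "size": 2,
                                        "n_children_under6": 0, "n_cars": 0}

    def test_household_round_trip(self, tmp_path):
        hh = pd.DataFrame({"HId": [1, 2], "type": ["couple", "single"],
                           "size": [3, 1], "n_children_under6": [1, 0],
                           "n_cars": [1, 0]})
        path = tmp_path / "h.csv"
        eval_io.write_household_table(hh, path)
        pd.testing.assert_frame_equal(eval_io.read_household_table(path), hh)

    def _activities(self):
        return pd.DataFrame({
            "PId": [1, 1, 1], "activity_id": [1, 2, 3],
            "purpose": ["Home", "Work", "Home"],
            "start_h": [3.0, 8.5, 17.9], "end_h": [7.7, 17.1, 3.0],
            "mode": ["", "Car", "Car"], "building_id": [11, 42, 11],
            "building_type": ["Apartment", "Other", "Apartment"],
            "x": [1500.3, 2200.1, 1500.3], "y": [300.0, 850.2, 300.0],
            "zone_id": ["Z1", "Z2", "Z1"]})

    def test_activity_table_round_trip(self, tmp_path):
        path = tmp_path / "a.csv"
        eval_io.write_activity_table(self._activities(), path)
        pd.testing.assert_frame_equal(eval_io.read_activity_table(path),
                                      self._activities())

    def test_times_serialized_with_one_decimal(self, tmp_path):
        path = tmp_path / "a.csv"
        eval_io.write_activity_table(self._activities(), path)
        assert "3.0,7.7" in path.read_text()

    def test_unknown_purpose_rejected_with_row(self, tmp_path):
        table = self._activities()
        table.loc[1, "purpose"] = "Gym"
        path = tmp_path / "a.csv"
        table_fixed = table.copy()
        eval_io.write_activity_table(table_fixed, path)
        with pytest.raises(ValidationError, match="row 3"):
            eval_io.read_activity_table(path)

    def test_unknown_marital_status_rejected(self, tmp_path):
        persons = self._persons()
        path = tmp_path / "p.csv"
        eval_io.write_person_table(persons, path)
        text = path.read_text().replace("couple", "married")
        path.write_text(text)
        with pytest.raises(ValidationError):
            eval_io.read_person_table(path)

    def test_pipeline_tables_round_trip(self, midscale_result, tmp_path):
        eval_io.write_activity_table(midscale_result.activity_table,
                                     tmp_path / "a.csv")
        back = eval_io.read_activity_table(tmp_path / "a.csv")
        assert len(back) == len(midscale_result.activity_table)
        pd.testing.assert_series_equal(
            back["start_h"], midscale_result.activity_table["start_h"]
            .astype(float).round(1), check_names=False)
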