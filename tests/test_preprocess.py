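import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from inrcast.preprocess import (
    Standardizer,
    apply_exclusion_filters,
    compute_bsa,
    consolidate_daily,
    extract_windows,
    fit_standardizer,
    select_chain_eval_cases,
)
from tests.conftest import make_records


class TestBsa:
    @pytest.mark.parametrize("height,weight,expected", [
        (180.0, 80.0, 2.0),
        (160.0, 56.25, 1.5811388300841898),   # sqrt(160*56.25/3600)
        (130.0, 35.0, 1.1242219627122576),    # lower filter bounds
    ])
    def test_mosteller_formula(self, height, weight, expected):
        assert compute_bsa(height, weight) == pytest.approx(expected, abs=1e-5)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_bsa(0.0, 70.0)
        with pytest.raises(ValueError):
            compute_bsa(170.0, -1.0)


class TestConsolidate:
    def test_two_inrs_last_policy(self):
        raw = make_records([("A", 1, 2.1, 3.0)])
        raw = pd.concat([raw, raw.assign(inr=2.4, dose_mg=0.0,
                                         administered=0)], ignore_index=True)
        out = consolidate_daily(raw, inr_policy="last")
        assert len(out) == 1
        assert out.loc[0, "inr"] == 2.4
        # non-administered dose contributes nothing
        assert out.loc[0, "dose_mg"] == 3.0

    def test_mean_policy(self):
        raw = make_records([("A", 1, 2.1, 3.0), ("A", 1, 2.4, 0.0)])
        out = consolidate_daily(raw, inr_policy="mean")
        assert out.loc[0, "inr"] == pytest.approx(2.25)
        assert out.loc[0, "dose_mg"] == 3.0

    def test_single_rows_unchanged(self):
        raw = make_records([("A", 1, 2.0, 5.0), ("A", 2, 2.2, 5.0)])
        out = consolidate_daily(raw)
        assert out["inr"].tolist() == [2.0, 2.2]
        assert out["dose_mg"].tolist() == [5.0, 5.0]

    def test_conflicting_statics_raise(self):
        raw = make_records([("A", 1, 2.0, 5.0), ("A", 2, 2.2, 5.0)])
        raw.loc[1, "weight_kg"] = 80.0
        with pytest.raises(ValueError, match="A"):
            consolidate_daily(raw)


class TestExclusionFilters:
    BOUNDARY_CASES = [
        # (column, retained value, excluded value)
        ("weight_kg", 35.0, 34.9),
        ("weight_kg", 120.0, 120.1),
        ("height_cm", 130.0, 129.9),
        ("height_cm", 220.0, 220.1),
    ]

    @pytest.mark.parametrize("col,keep_val,drop_val", BOUNDARY_CASES)
    def test_patient_level_boundaries_are_strict(self, col, keep_val, drop_val):
        raw = make_records([("KEEP", 1, 2.0, 5.0), ("DROP", 1, 2.0, 5.0)])
        raw.loc[raw.patient_id == "KEEP", col] = keep_val
        raw.loc[raw.patient_id == "DROP", col] = drop_val
        kept, log = apply_exclusion_filters(consolidate_daily(raw))
        assert set(kept["patient_id"]) == {"KEEP"}
        assert sum(log.patients_excluded.values()) == 1

    def test_inr_boundary_record_level(self):
        raw = make_records([("A", 1, 10.0, 5.0), ("A", 2, 10.1, 5.0)])
        kept, log = apply_exclusion_filters(consolidate_daily(raw))
        assert kept["inr"].tolist() == [10.0]
        assert log.records_excluded["inr_gt_10"] == 1

    def test_dose_boundary_record_level(self):
        raw = make_records([("A", 1, 2.0, 20.0), ("A", 2, 2.0, 20.5)])
        kept, log = apply_exclusion_filters(consolidate_daily(raw))
        assert kept["dose_mg"].tolist() == [20.0]
        assert log.records_excluded["dose_gt_20"] == 1

    def test_multiple_daily_doses_excludes_patient(self):
        raw = make_records([("A", 1, 2.0, 5.0), ("A", 2, 2.0, 5.0),
                            ("B", 1, 2.0, 5.0)])
        raw.loc[1, "doses_per_day"] = 2
        kept, log = apply_exclusion_filters(consolidate_daily(raw))
        assert set(kept["patient_id"]) == {"B"}
        assert log.patients_excluded["multiple_daily_doses"] == 1

    def test_under_18_excluded(self):
        raw = make_records([("A", 1, 2.0, 5.0), ("B", 1, 2.0, 5.0)])
        raw.loc[raw.patient_id == "A", "age"] = 17
        kept, log = apply_exclusion_filters(consolidate_daily(raw))
        assert set(kept["patient_id"]) == {"B"}
        assert log.patients_excluded["age_lt_18"] == 1


def _brute_force_windows(days, inr, dose, length=5):
    """Oracle: test every contiguous 5-subsequence directly."""
    n = 0
    for i in range(len(days)):
        want = [days[i] + k for k in range(length)]
        idx = [list(days).index(d) for d in want if d in list(days)]
        if len(idx) < length:
            continue
        if all(np.isfinite(inr[j]) and dose[j] > 0 for j in idx):
            n += 1
    return n


class TestWindows:
    def test_five_days_one_sample(self):
        raw = make_records([("A", d, 2.0 + 0.1 * d, 5.0) for d in range(1, 6)])
        w = extract_windows(consolidate_daily(raw))
        assert len(w) == 1
        assert w.loc[0, "target_inr"] == pytest.approx(2.5)
        assert [w.loc[0, f"inr{i}"] for i in range(1, 5)] == \
            pytest.approx([2.1, 2.2, 2.3, 2.4])

    def test_eight_days_four_samples(self):
        raw = make_records([("A", d, 2.0, 5.0) for d in range(1, 9)])
        assert len(extract_windows(consolidate_daily(raw))) == 4

    def test_gap_breaks_windows(self):
        raw = make_records([("A", d, 2.0, 5.0) for d in (1, 2, 3, 5, 6)])
        assert len(extract_windows(consolidate_daily(raw))) == 0

    def test_zero_dose_breaks_windows(self):
        raw = make_records([("A", d, 2.0, 5.0 if d != 3 else 0.0)
                            for d in range(1, 9)])
        # eligible runs must avoid day 3: only days 4-8 remain
        assert len(extract_windows(consolidate_daily(raw))) == 1

    def test_windows_never_span_patients(self):
        rows = ([("A", d, 2.0, 5.0) for d in range(1, 4)]
                + [("B", d, 2.0, 5.0) for d in range(4, 11)])
        w = extract_windows(consolidate_daily(make_records(rows)))
        assert set(w["patient_id"]) == {"B"}
        assert len(w) == 3

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_pat = data.draw(st.integers(1, 8))
        rows = []
        per_patient = {}
        for p in range(n_pat):
            days = sorted(data.draw(st.sets(st.integers(1, 15),
                                            min_size=0, max_size=12)))
            inrs, doses = [], []
            for d in days:
                inr = data.draw(st.floats(0.8, 5.0))
                dose = data.draw(st.sampled_from([0.0, 2.0, 5.0]))
                rows.append((f"P{p}", d, inr, dose))
                inrs.append(inr)
                doses.append(dose)
            per_patient[f"P{p}"] = (np.array(days), np.array(inrs),
                                    np.array(doses))
        if not rows:
            return
        w = extract_windows(consolidate_daily(make_records(rows)))
        expected = sum(_brute_force_windows(*v) for v in per_patient.values())
        assert len(w) == expected


class TestChainCases:
    @staticmethod
    def _records(doses):
        return make_records([
            ("A", d + 1, 2.0, doses[d]) for d in range(len(doses))])

    def test_fixed_day4_to_7_eligible(self):
        cases = select_chain_eval_cases(consolidate_daily(
            self._records([5, 5.5, 4, 3, 3, 3, 3, 4])))
        assert len(cases) == 1
        assert cases.loc[0, "fixed_dose"] == 3.0
        assert cases.loc[0, "actual_day8_inr"] == 2.0

    def test_varying_day4_to_7_ineligible(self):
        cases = select_chain_eval_cases(consolidate_daily(
            self._records([5, 5, 5, 3, 3, 3.5, 3, 4])))
        assert len(cases) == 0

    def test_seven_days_ineligible(self):
        cases = select_chain_eval_cases(consolidate_daily(
            self._records([3, 3, 3, 3, 3, 3, 3])))
        assert len(cases) == 0


class TestStandardizer:
    def _windows(self, rng, n=40):
        raw = make_records([
            (f"P{i}", d, rng.uniform(1, 4), rng.uniform(1, 9))
            for i in range(n) for d in range(1, 6)])
        raw["age"] = np.repeat(rng.integers(20, 90, n), 5)
        raw["weight_kg"] = np.repeat(rng.uniform(40, 110, n), 5)
        raw["height_cm"] = np.repeat(rng.uniform(140, 190, n), 5)
        raw["sex"] = np.repeat(np.where(rng.random(n) < 0.5, "M", "F"), 5)
        return extract_windows(consolidate_daily(raw))

    def test_training_features_have_unit_moments(self, rng):
        w = self._windows(rng)
        std = fit_standardizer(w)
        xs, xq, y = std.transform_windows(w)
        assert np.allclose(xs.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(xs.std(axis=0, ddof=1), 1.0, atol=1e-6)
        assert abs(y.mean()) < 1e-6 and abs(y.std(ddof=1) - 1) < 1e-6
        # series channels pooled over the 4 days
        assert abs(xq[..., 0].mean()) < 1e-6
        assert abs(xq[..., 1].mean()) < 1e-6

    def test_round_trip_identity(self, rng):
        w = self._windows(rng)
        std = fit_standardizer(w)
        for name in ("age", "inr", "dose", "target_inr"):
            v = rng.uniform(0.5, 9.0, size=50)
            back = std.inverse_value(name, std.transform_value(name, v))
            assert np.allclose(back, v, atol=1e-9)

    def test_two_point_feature(self):
        std = Standardizer(means={"age": 2.0}, sds={"age": np.std([1.0, 3.0],
                                                                  ddof=1)})
        z = std.transform_value("age", [1.0, 3.0])
        # sample-sd convention: {1, 3} -> {-1/sqrt(2), +1/sqrt(2)} * sqrt(2)
        assert z == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_zero_variance_feature_raises(self, rng):
        w = self._windows(rng)
        w["age"] = 50.0
        with pytest.raises(ValueError, match="age"):
            fit_standardizer(w)

    def test_json_round_trip(self, rng):
        w = self._windows(rng)
        std = fit_standardizer(w)
        back = Standardizer.from_json(std.to_json())
        assert back.means == std.means and back.sds == std.sds
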