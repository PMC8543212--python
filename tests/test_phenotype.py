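"""Phenotype rules: imputation, eligibility, exposure, outcome derivation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coolmatch import (
    consecutive_run,
    derive_exposure,
    derive_outcomes,
    impute_cooling_day2,
    select_cohort,
    suppress_small_counts,
)
from coolmatch.config import DataError

from conftest import make_daily, make_infant, simple_stay


def _cooling_daily(cooled, death_day=None):
    rows = []
    for day, flag in enumerate(cooled, start=1):
        rows.append({"infant_id": "A", "day": day, "cooled": flag,
                     "died_today": int(death_day == day)})
    return make_daily(rows)


class TestImputeCoolingDay2:
    def test_missing_between_cooled_days_is_imputed(self):
        out = impute_cooling_day2(_cooling_daily([1.0, np.nan, 1.0]))
        assert out["cooled"].tolist() == [1.0, 1.0, 1.0]

    def test_not_imputed_when_day3_not_cooled(self):
        daily = _cooling_daily([1.0, np.nan, 0.0])
        out = impute_cooling_day2(daily)
        pd.testing.assert_frame_equal(out, daily)

    def test_not_imputed_when_death_during_cooling(self):
        daily = _cooling_daily([1.0, np.nan, 1.0], death_day=3)
        out = impute_cooling_day2(daily)
        assert np.isnan(out["cooled"].iloc[1])

    def test_recorded_day2_left_untouched(self):
        daily = _cooling_daily([1.0, 0.0, 1.0])
        out = impute_cooling_day2(daily)
        pd.testing.assert_frame_equal(out, daily)

    def test_idempotent(self, cohort_small):
        _, _, daily, _ = cohort_small
        once = impute_cooling_day2(daily)
        twice = impute_cooling_day2(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_non_contiguous_days_rejected(self):
        daily = make_daily([{"infant_id": "A", "day": 1, "cooled": 1.0},
                            {"infant_id": "A", "day": 3, "cooled": 1.0}])
        with pytest.raises(DataError):
            impute_cooling_day2(daily)


class TestSelectCohort:
    def _run(self, ga_weeks, ga_days, cooled, death_day=None):
        infants = pd.DataFrame([make_infant(ga_weeks=ga_weeks,
                                            ga_days=ga_days)])
        daily = _cooling_daily(cooled, death_day)
        eligible, exclusions = select_cohort(infants, daily)
        return eligible, exclusions

    def test_gestation_just_below_threshold_excluded(self):
        eligible, excl = self._run(35, 6, [1.0, 1.0, 1.0])
        assert eligible == []
        assert excl["reason"].tolist() == ["gestation_below_36"]

    def test_gestation_exactly_36_0_included(self):
        eligible, _ = self._run(36, 0, [1.0, 1.0, 1.0])
        assert eligible == ["A"]

    def test_death_during_cooling_included(self):
        eligible, _ = self._run(40, 0, [1.0, 1.0], death_day=2)
        assert eligible == ["A"]

    def test_incomplete_cooling_without_death_excluded(self):
        eligible, excl = self._run(40, 0, [1.0, 1.0, 0.0])
        assert eligible == []
        assert excl["reason"].tolist() == ["incomplete_cooling"]

    def test_year_out_of_range_excluded(self):
        infants = pd.DataFrame([make_infant(birth_year=2009)])
        daily = _cooling_daily([1.0, 1.0, 1.0])
        eligible, excl = select_cohort(infants, daily, years=(2010, 2017))
        assert eligible == [] and excl["reason"].tolist() == ["year_out_of_range"]

    def test_no_daily_records_excluded(self):
        infants = pd.DataFrame([make_infant()])
        daily = make_daily([])
        eligible, excl = select_cohort(infants, daily)
        assert eligible == [] and excl["reason"].tolist() == ["no_daily_records"]

    def test_eligibility_monotone_in_cooling_completeness(self):
        """Turning any non-cooled day flag to cooled never removes eligibility."""
        for pattern in itertools.product([0.0, 1.0, np.nan], repeat=3):
            base, _ = self._run(40, 0, list(pattern))
            for i in range(3):
                if pattern[i] == 1.0:
                    continue
                upgraded = list(pattern)
                upgraded[i] = 1.0
                up, _ = self._run(40, 0, upgraded)
                assert set(base) <= set(up), (pattern, upgraded)


class TestDeriveExposure:
    def test_pn_on_cooled_day_is_exposed(self):
        daily = make_daily(simple_stay("A", 6, pn=[2]))
        assert derive_exposure(daily, ["A"]).loc["A"]

    def test_pn_only_after_cooling_is_unexposed(self):
        daily = make_daily(simple_stay("A", 6, pn=[5]))
        assert not derive_exposure(daily, ["A"]).loc["A"]

    def test_missing_pn_flags_are_unexposed(self):
        rows = simple_stay("A", 6)
        daily = make_daily(rows)
        daily["pn"] = np.nan
        assert not derive_exposure(daily, ["A"]).loc["A"]


class TestConsecutiveRun:
    @pytest.mark.parametrize("days,expected", [
        (range(4, 9), True),    # days 4-8: qualifies
        (range(3, 8), False),   # run starts on day 3
        (range(4, 8), False),   # only 4 days
    ])
    def test_pragmatic_rule_examples(self, days, expected):
        flags = [d in set(days) for d in range(1, 15)]
        assert consecutive_run(flags, min_len=5, start_after_day=3) is expected

    def test_empty_sequence_false(self):
        assert consecutive_run([], 5, 3) is False

    def test_min_len_must_be_positive(self):
        with pytest.raises(ValueError):
            consecutive_run([True], 0, 3)

    @given(st.lists(st.booleans(), max_size=60),
           st.integers(1, 8), st.integers(0, 6))
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_window_scan(self, flags, min_len,
                                             start_after):
        def brute(flags, min_len, start_after):
            n = len(flags)
            for start in range(1, n + 1):
                if start <= start_after:
                    continue
                if start > 1 and flags[start - 2]:
                    continue  # not the start of a maximal run
                length = 0
                for d in range(start - 1, n):
                    if flags[d]:
                        length += 1
                    else:
                        break
                if length >= min_len:
                    return True
            return False

        assert consecutive_run(flags, min_len, start_after) \
            == brute(flags, min_len, start_after)


class TestDeriveOutcomes:
    def test_culture_on_day_3_does_not_count(self):
        rows = simple_stay("A", 8)
        rows[2]["blood_culture"] = "pathogen"  # day 3
        infants = pd.DataFrame([make_infant()])
        out = derive_outcomes(infants, make_daily(rows), ["A"])
        assert not out["culture_positive_loi"].iloc[0]

    def test_commensal_growth_does_not_count(self):
        rows = simple_stay("A", 8)
        rows[5]["blood_culture"] = "commensal"  # day 6
        infants = pd.DataFrame([make_infant()])
        out = derive_outcomes(infants, make_daily(rows), ["A"])
        assert not out["culture_positive_loi"].iloc[0]

    def test_pathogen_on_day_4_counts(self):
        rows = simple_stay("A", 8)
        rows[3]["blood_culture"] = "pathogen"  # day 4
        infants = pd.DataFrame([make_infant()])
        out = derive_outcomes(infants, make_daily(rows), ["A"])
        assert out["culture_positive_loi"].iloc[0]

    def test_pragmatic_nec_requires_nbm_on_every_run_day(self):
        infants = pd.DataFrame([make_infant(infant_id="A"),
                                make_infant(infant_id="B")])
        rows = simple_stay("A", 12, antibiotics=range(5, 10),
                           nil_by_mouth=range(5, 10))
        rows[4]["nec_diagnosis_recorded"] = 1
        rows_b = simple_stay("B", 12, antibiotics=range(5, 10),
                             nil_by_mouth=range(5, 9))  # one NBM day short
        rows_b[4]["nec_diagnosis_recorded"] = 1
        out = derive_outcomes(infants, make_daily(rows + rows_b), ["A", "B"])
        out = out.set_index("infant_id")
        assert out.loc["A", "pragmatic_nec"]
        assert not out.loc["B", "pragmatic_nec"]

    def test_weight_equal_to_reference_mean_gives_sds_zero(self):
        from coolmatch import growth
        mean, _ = growth.reference_mean_sd(1, 40)  # male, 39 weeks + 8 days
        infants = pd.DataFrame([make_infant(ga_weeks=39, ga_days=0,
                                            discharge_weight_g=float(mean))])
        daily = make_daily(simple_stay("A", 8))
        out = derive_outcomes(infants, daily, ["A"])
        assert out["discharge_weight_sds"].iloc[0] == pytest.approx(0.0)

    def test_length_of_stay_and_line_day_invariants(self, analysis_small):
        a = analysis_small
        assert (a["length_of_stay"] >= 1).all()
        assert (a["central_line_days"] <= a["length_of_stay"]).all()
        assert (a["pn_duration_days"] >= 0).all()

    def test_derived_outcomes_equal_ground_truth(self, cohort_small,
                                                 analysis_small):
        _, infants, daily, gt = cohort_small
        a = analysis_small.set_index("infant_id")
        t = gt.table.set_index("infant_id").loc[a.index]
        assert (a["exposure_pn"].astype(int) == t["exposed"]).all()
        for col in ("survived", "culture_positive_loi", "pragmatic_loi",
                    "pragmatic_nec", "hypoglycaemia",
                    "breastfeeding_at_discharge"):
            assert (a[col].astype(int) == t[col]).all(), col
        for col in ("length_of_stay", "central_line_days",
                    "pn_duration_days"):
            assert (a[col] == t[col]).all(), col
        np.testing.assert_allclose(a["discharge_weight_sds"],
                                   t["discharge_weight_sds"], atol=1e-9)


@pytest.mark.parametrize("count,expected", [
    (0, "0"), (1, "<5"), (4, "<5"), (5, "5"), (11, "11"),
])
def test_suppress_small_counts(count, expected):
    assert suppress_small_counts(count) == expected


def test_suppress_small_counts_negative_rejected():
    with pytest.raises(ValueError):
        suppress_small_counts(-1)
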