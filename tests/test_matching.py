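"""Stratified replicated matching: strata, deciles, pairing, balance."""

import numpy as np
import pandas as pd
import pytest

from coolmatch import (
    assign_strata,
    balance_table,
    match_once,
    propensity_deciles,
    replicate_matching,
)
from coolmatch.config import ConfigurationError
from coolmatch.matching import ph_band, year_bands


class TestStrata:
    def test_ph_banding(self):
        assert ph_band(6.95) == "6.9-7.0"
        assert ph_band(7.0) == "6.9-7.0"      # closed upper bound
        assert ph_band(7.01) == ">7.0"
        assert ph_band(6.89) == "<6.9"
        assert ph_band(float("nan")) == "missing"

    def test_year_bands_are_two_year_windows(self):
        assert year_bands((2010, 2017)) == [(2010, 2011), (2012, 2013),
                                            (2014, 2015), (2016, 2017)]

    def test_assign_strata_examples(self):
        df = pd.DataFrame({
            "birth_year": [2010, 2017, 2013],
            "cord_ph_band": ["6.9-7.0", "missing", ">7.0"],
        })
        labels = assign_strata(df, (2010, 2017))
        assert labels.tolist() == ["2010-2011|6.9-7.0", "2016-2017|missing",
                                   "2012-2013|>7.0"]

    def test_strict_12_group_mode_drops_missing_ph(self):
        df = pd.DataFrame({"birth_year": [2010, 2011],
                           "cord_ph_band": ["missing", "<6.9"]})
        labels = assign_strata(df, (2010, 2017), include_missing_ph=False)
        assert labels.isna().tolist() == [True, False]

    def test_year_outside_range_rejected(self):
        df = pd.DataFrame({"birth_year": [2009], "cord_ph_band": [">7.0"]})
        with pytest.raises(ConfigurationError):
            assign_strata(df, (2010, 2017))

    def test_every_infant_maps_to_one_stratum(self, analysis_small):
        labels = assign_strata(analysis_small, (2010, 2017))
        assert labels.notna().all()
        assert labels.nunique() <= 16


class TestDeciles:
    def test_100_distinct_scores_give_10_groups_of_10(self):
        scores = pd.Series(np.linspace(0.01, 0.99, 100))
        strata = pd.Series(["s"] * 100)
        d = propensity_deciles(scores, strata)
        assert d.value_counts().tolist() == [10] * 10

    def test_all_tied_scores_form_single_group(self):
        scores = pd.Series([0.4] * 50)
        d = propensity_deciles(scores, pd.Series(["s"] * 50))
        assert d.nunique() == 1

    def test_23_infants_group_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.uniform(0.05, 0.95, 23))
        d = propensity_deciles(scores, pd.Series(["s"] * 23))
        sizes = d.value_counts()
        assert len(sizes) == 10 and sizes.max() - sizes.min() <= 1

    def test_computed_within_stratum(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.uniform(0.1, 0.9, 40))
        strata = pd.Series(["a"] * 20 + ["b"] * 20)
        d = propensity_deciles(scores, strata)
        for lab in ("a", "b"):
            assert d[strata == lab].value_counts().tolist() == [2] * 10

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            propensity_deciles(pd.Series([0.5, 1.0]), pd.Series(["s", "s"]))


def _toy_analysis(n_exposed, n_unexposed, stratum="2010-2011|>7.0"):
    n = n_exposed + n_unexposed
    df = pd.DataFrame({
        "infant_id": [f"I{i:03d}" for i in range(n)],
        "exposure_pn": [True] * n_exposed + [False] * n_unexposed,
    })
    strata = pd.Series([stratum] * n)
    deciles = pd.Series([0] * n, dtype="Int64")
    return df, strata, deciles


class TestMatchOnce:
    def test_min_rule_pair_count(self):
        df, strata, deciles = _toy_analysis(3, 5)
        ps = match_once(df, strata, deciles, seed=1)
        assert len(ps) == 3

    def test_empty_side_gives_no_pairs(self):
        df, strata, deciles = _toy_analysis(0, 5)
        ps = match_once(df, strata, deciles, seed=1)
        assert len(ps) == 0

    def test_same_seed_reproduces_pairs(self):
        df, strata, deciles = _toy_analysis(10, 14)
        a = match_once(df, strata, deciles, seed=9)
        b = match_once(df, strata, deciles, seed=9)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_no_infant_reused_within_replication(self, analysis_small):
        from coolmatch import default_spec, build_design_matrix, fit_propensity
        X, _ = build_design_matrix(analysis_small, default_spec())
        fit = fit_propensity(X, analysis_small["exposure_pn"].astype(int))
        strata = assign_strata(analysis_small, (2010, 2017))
        deciles = propensity_deciles(fit.scores, strata)
        ps = match_once(analysis_small, strata, deciles, seed=3)
        ids = ps.all_ids()
        assert len(ids) == len(set(ids))
        # both members share stratum and decile by construction
        a = analysis_small.set_index("infant_id")
        s = strata.set_axis(analysis_small["infant_id"])
        d = deciles.set_axis(analysis_small["infant_id"])
        assert (s[ps.pairs["exposed_id"]].to_numpy()
                == s[ps.pairs["unexposed_id"]].to_numpy()).all()
        assert (d[ps.pairs["exposed_id"]].to_numpy()
                == d[ps.pairs["unexposed_id"]].to_numpy()).all()
        assert a.loc[ps.pairs["exposed_id"], "exposure_pn"].all()
        assert not a.loc[ps.pairs["unexposed_id"], "exposure_pn"].any()


class TestReplication:
    def test_m_equals_one_reduces_to_match_once(self):
        df, strata, deciles = _toy_analysis(5, 7)
        single = match_once(df, strata, deciles, seed=11, replication=1)
        reps = replicate_matching(df, strata, deciles, m=1, base_seed=10)
        pd.testing.assert_frame_equal(reps[0].pairs, single.pairs)

    def test_pair_count_identical_across_replications(self):
        df, strata, deciles = _toy_analysis(40, 60)
        reps = replicate_matching(df, strata, deciles, m=25, base_seed=2)
        counts = {len(r) for r in reps}
        assert counts == {40}

    def test_different_base_seeds_same_count_different_pairs(self):
        df, strata, deciles = _toy_analysis(40, 60)
        a = replicate_matching(df, strata, deciles, m=1, base_seed=1)[0]
        b = replicate_matching(df, strata, deciles, m=1, base_seed=100)[0]
        assert len(a) == len(b)
        assert not a.pairs.equals(b.pairs)

    def test_m_below_one_rejected(self):
        df, strata, deciles = _toy_analysis(2, 2)
        with pytest.raises(ConfigurationError):
            replicate_matching(df, strata, deciles, m=0, base_seed=1)


@pytest.fixture(scope="session")
def matched(analysis_small):
    from coolmatch import default_spec, build_design_matrix, fit_propensity
    X, _ = build_design_matrix(analysis_small, default_spec())
    fit = fit_propensity(X, analysis_small["exposure_pn"].astype(int))
    strata = assign_strata(analysis_small, (2010, 2017))
    deciles = propensity_deciles(fit.scores, strata)
    reps = replicate_matching(analysis_small, strata, deciles, m=5,
                              base_seed=4)
    return analysis_small, reps


class TestBalance:
    def test_exact_match_variable_perfectly_balanced(self, matched):
        analysis, reps = matched
        tbl = balance_table(analysis, reps, ["cord_ph_band"])
        assert (tbl["smd_post"].abs() < 1e-12).all()

    def test_confounded_covariates_improve_after_matching(self, matched):
        analysis, reps = matched
        tbl = balance_table(analysis, reps,
                            ["inotropes_day1", "ventilated_day1",
                             "chest_compressions"]).set_index("covariate")
        assert (tbl["smd_post"].abs() < tbl["smd_pre"].abs()).all()

    def test_independent_covariate_near_zero_pre_smd(self, matched):
        analysis, reps = matched
        tbl = balance_table(analysis, reps, ["caesarean"])
        assert abs(tbl["smd_pre"].iloc[0]) < 0.1
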