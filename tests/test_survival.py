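import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from radsurv.survival import (
    holm_bonferroni,
    impute_censored,
    km_estimate,
    km_report_table,
    logrank,
    median_split_km,
    screen_group,
    spearman,
)

from _oracles import brute_holm, brute_logrank, brute_spearman_rho


class TestImputation:
    def test_censored_between_deaths_gets_mean_of_later_deaths(self):
        out = impute_censored([10, 20, 30, 15], [1, 1, 1, 0])
        assert out.tolist() == [10, 20, 30, 25]  # mean{20, 30}

    def test_censored_before_all_deaths_gets_grand_mean(self):
        out = impute_censored([10, 20, 30, 5], [1, 1, 1, 0])
        assert out[-1] == pytest.approx(20.0)

    def test_censored_beyond_all_deaths_keeps_time(self):
        out = impute_censored([10, 20, 30, 40], [1, 1, 1, 0])
        assert out[-1] == 40.0

    def test_identity_on_fully_uncensored(self, rng):
        t = rng.exponential(100, size=30)
        np.testing.assert_array_equal(impute_censored(t, np.ones(30, int)), t)

    def test_never_decreases_any_time(self, rng):
        t = rng.exponential(100, size=50)
        e = rng.integers(0, 2, size=50)
        if e.sum() == 0:
            e[0] = 1
        assert (impute_censored(t, e) >= t).all()

    def test_all_censored_errors(self):
        with pytest.raises(ValueError, match="uncensored"):
            impute_censored([1, 2], [0, 0])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 3.0, 7.0, 11.0])[0] == pytest.approx(1.0)
        assert spearman(x, list(reversed(x)))[0] == pytest.approx(-1.0)

    def test_hand_ranked_five_point_example(self):
        rho, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        assert 0 < p < 1

    def test_constant_vector_convention(self):
        assert spearman([1, 1, 1, 1], [1, 2, 3, 4]) == (0.0, 1.0)

    def test_matches_independent_rank_oracle_with_ties(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.integers(0, 5, size=20).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            x[0] += 1
            y[0] += 1
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(brute_spearman_rho(x, y), abs=1e-12)


class TestHolm:
    def test_two_p_step_down(self):
        p_adj, reject = holm_bonferroni([0.01, 0.04], alpha=0.05)
        np.testing.assert_allclose(p_adj, [0.02, 0.04])
        assert reject.tolist() == [True, True]

    def test_single_p_unchanged(self):
        p_adj, _ = holm_bonferroni([0.037])
        assert p_adj[0] == pytest.approx(0.037)

    def test_matches_direct_step_down_oracle(self, rng):
        p = rng.random(25)
        p_adj, reject = holm_bonferroni(p)
        ref_adj, ref_rej = brute_holm(list(p))
        np.testing.assert_allclose(p_adj, ref_adj, atol=1e-12)
        assert reject.tolist() == ref_rej

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(40)
        p_adj, _ = holm_bonferroni(p)
        assert (np.diff(p_adj[np.argsort(p)]) >= -1e-15).all()
        assert (p_adj >= p).all()


class TestKM:
    def test_product_limit_hand_example(self):
        kmf, median = km_estimate([1, 2, 3], [1, 1, 1])
        sf = kmf.survival_function_at_times([1, 2, 3]).to_numpy()
        np.testing.assert_allclose(sf, [2 / 3, 1 / 3, 0.0])
        assert median == 2.0  # smallest t with S(t) <= 0.5

    def test_single_censored_patient_flat_curve(self):
        kmf, median = km_estimate([10], [0])
        assert kmf.survival_function_at_times([10]).iloc[0] == 1.0
        assert np.isinf(median)

    def test_no_censoring_reduces_to_empirical_survivor(self, rng):
        t = rng.exponential(10, size=40)
        kmf, _ = km_estimate(t, np.ones(40, int))
        for q in [np.quantile(t, x) for x in (0.25, 0.5, 0.9)]:
            assert kmf.survival_function_at_times([q]).iloc[0] == pytest.approx(
                (t > q).mean()
            )


class TestLogrank:
    def test_identical_arms_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        res = logrank(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_shifted_arm_detected_with_hr_direction(self):
        ta = np.arange(1.0, 21.0)
        tb = ta * 10
        res = logrank(ta, np.ones(20, int), tb, np.ones(20, int))
        assert res.chi2 > 10
        assert res.hazard_ratio > 1  # arm A dies faster

    def test_hand_sized_example_matches_risk_table_oracle(self):
        ta, ea = [1.0, 2.0, 5.0], [1, 1, 0]
        tb, eb = [3.0, 4.0, 6.0], [1, 1, 1]
        res = logrank(ta, ea, tb, eb)
        chi2_ref, (oa, ea_ref), _ = brute_logrank(ta, ea, tb, eb)
        assert res.chi2 == pytest.approx(chi2_ref)
        assert res.observed[0] == oa
        assert res.expected[0] == pytest.approx(ea_ref)

    def test_agrees_with_lifelines(self, rng):
        ta = rng.exponential(10, 30)
        tb = rng.exponential(20, 25)
        ea = rng.integers(0, 2, 30)
        eb = rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        res = logrank(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_label_swap_inverts_hr_and_keeps_chi2(self, rng):
        ta = rng.exponential(10, 25)
        tb = rng.exponential(25, 25)
        ea = np.ones(25, int)
        eb = rng.integers(0, 2, 25)
        r1 = logrank(ta, ea, tb, eb)
        r2 = logrank(tb, eb, ta, ea)
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.hazard_ratio == pytest.approx(1 / r2.hazard_ratio, rel=1e-9)

    def test_cox_hr_close_to_oe_hr(self, rng):
        ta = rng.exponential(10, 60)
        tb = rng.exponential(30, 60)
        e = np.ones(60, int)
        oe = logrank(ta, e, tb, e, hr_method="oe").hazard_ratio
        cox = logrank(ta, e, tb, e, hr_method="cox").hazard_ratio
        assert oe == pytest.approx(cox, rel=0.25)


class TestMedianSplit:
    @staticmethod
    def toy_group(rng, n=40, effect=2.0):
        feat = rng.random(n)
        lam = 0.01 * np.exp(effect * feat)
        time = rng.exponential(1 / lam)
        return pd.DataFrame(
            {"f": feat, "time": time, "event": np.ones(n, int), "age": 60.0}
        )

    def test_planted_effect_direction(self, rng):
        group = self.toy_group(rng, n=120, effect=2.5)
        rep = median_split_km(group, "f")
        assert rep.hazard_ratio > 1  # above-median arm dies faster
        assert rep.median_below > rep.median_above
        assert rep.n_below + rep.n_above == 120

    def test_all_values_identical_is_degenerate(self, rng):
        group = self.toy_group(rng)
        group["f"] = 1.0
        rep = median_split_km(group, "f")
        assert rep.degenerate

    def test_cutoff_is_group_median(self, rng):
        group = self.toy_group(rng)
        rep = median_split_km(group, "f")
        assert rep.cutoff == pytest.approx(float(group["f"].median()))


class TestScreen:
    @staticmethod
    def null_cohort_frame(rng, n=120):
        return pd.DataFrame(
            {
                "grp": rng.choice(["A", "B"], size=n),
                "age": rng.normal(65, 8, n),
                "x1": rng.random(n),
                "x2": rng.random(n),
                "time": rng.exponential(300, n),
                "event": rng.integers(0, 2, n),
            }
        )

    def test_duplicate_feature_column_identical_rho(self, rng):
        df = self.null_cohort_frame(rng)
        df["x3"] = df["x1"]
        res = screen_group(df, "grp", features=["x1", "x2", "x3"], include_age=False)
        a = res[res.feature == "x1"].set_index("group")["rho"]
        b = res[res.feature == "x3"].set_index("group")["rho"]
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_family_is_groupwide(self, rng):
        df = self.null_cohort_frame(rng)
        res = screen_group(df, "grp", features=["x1", "x2"])
        assert res["family_size"].iloc[0] == len(res) == 2 * 3  # 2 groups x (2 + age)

    def test_uncensored_only_mode_restricts_to_deaths(self, rng):
        df = self.null_cohort_frame(rng)
        res = screen_group(df, "grp", features=["x1"], uncensored_only=True,
                           include_age=False)
        deaths = df[df.event == 1].groupby("grp").size()
        for _, row in res.iterrows():
            assert row["n"] == deaths[row["group"]]

    def test_small_group_skipped_with_warning(self, rng):
        df = self.null_cohort_frame(rng, n=30)
        df.loc[df.index[:2], "grp"] = "C"
        df = pd.concat([df[df.grp != "C"], df[df.grp == "C"].iloc[:2]])
        with pytest.warns(UserWarning, match="skipped"):
            res = screen_group(df, "grp", features=["x1"], include_age=False)
        assert "C" not in set(res["group"])


class TestKMReportTable:
    def test_reports_every_cell_with_family_correction(self, rng):
        df = TestScreen.null_cohort_frame(rng)
        res = km_report_table(df, "grp", features=["x1", "x2"], include_age=False)
        assert len(res) == 4
        tested = res[~res.degenerate]
        assert (tested.p_adj >= tested.p_raw - 1e-15).all()
        assert set(res.columns) >= {"cutoff", "median_below_days", "hazard_ratio"}
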