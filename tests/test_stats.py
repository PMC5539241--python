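import math

import numpy as np
import pytest
from scipy import stats as sps

from ceusvv import (
    GroupSummary,
    InvalidParameterError,
    UndefinedCorrelationError,
    dunnett_t3,
    friedman_test,
    group_comparison_report,
    one_way_anova,
    pearson_correlation,
    smm_sf,
    smm_sf_mc,
    t_test,
)


class TestTTest:
    def test_hand_evaluated_pooled_formula(self):
        # means 2 and 5, each variance 1, pooled sp2 = 1, se = sqrt(2/3)
        res = t_test([1, 2, 3], [4, 5, 6], "student")
        assert res.statistic == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))
        assert res.df == 4

    def test_identical_samples_null(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_matches_scipy_on_random_samples(self, variant, rng):
        for _ in range(50):
            a = rng.normal(0, 2, rng.integers(3, 20))
            b = rng.normal(1, 1, rng.integers(3, 20))
            res = t_test(a, b, variant)
            ref = sps.ttest_ind(a, b, equal_var=(variant == "student"))
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_summary_and_raw_inputs_bit_consistent(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 9)
        raw = t_test(a, b, "welch")
        summ = t_test(
            GroupSummary.from_sample("a", a), GroupSummary.from_sample("b", b), "welch"
        )
        assert raw.statistic == summ.statistic
        assert raw.p_value == summ.p_value

    def test_zero_variance_branches(self):
        same = t_test([2.0, 2.0], [2.0, 2.0])
        assert same.p_value == 1.0
        diff = t_test([2.0, 2.0], [3.0, 3.0])
        assert diff.p_value == 0.0
        assert "degenerate" in diff.note

    def test_printed_cholesterol_summaries_are_significant(self):
        """Summary-statistic test on total-cholesterol group summaries
        (18.948 +/- 4.633 vs 2.901 +/- 2.788, n = 10 each): p far below
        0.001, matching the printed bound."""
        res = t_test(
            GroupSummary("diet", 10, 18.948, 4.633),
            GroupSummary("control", 10, 2.901, 2.788),
            "student",
        )
        assert res.p_value < 0.001
        assert res.statistic > 0


class TestAnova:
    def test_equal_groups_give_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_evaluated_sums_of_squares(self):
        # SSB = 16 (df 2), SSW = 1.5 (df 3) -> F = 8 / 0.5 = 16
        res = one_way_anova([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(16.0)

    def test_matches_scipy_on_random_groups(self, rng):
        for _ in range(50):
            groups = [
                rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 12))
                for _ in range(rng.integers(2, 6))
            ]
            res = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_within_variance_flags_infinite_f(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert res.statistic == np.inf
        assert res.p_value == 0.0


class TestFriedman:
    def test_identical_rankings_reach_maximal_statistic(self):
        # k = 3 treatments ranked identically in b = 10 blocks -> 2b = 20
        X = np.tile([1.0, 2.0, 3.0], (10, 1)) + np.arange(10)[:, None]
        res = friedman_test(X)
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value == pytest.approx(sps.chi2.sf(20.0, 2))

    def test_constant_blocks_give_zero(self):
        X = np.tile(np.arange(8.0)[:, None], (1, 4))
        res = friedman_test(X)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_on_continuous_data(self, rng):
        for _ in range(30):
            X = rng.normal(0, 1, (rng.integers(5, 15), rng.integers(3, 6)))
            res = friedman_test(X)
            ref = sps.friedmanchisquare(*X.T)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_midrank_tie_correction_hand_case(self):
        # block ranks with one tie: ranks (1.5, 1.5, 3) twice
        X = np.array([[1.0, 1.0, 2.0], [3.0, 3.0, 7.0]])
        ranks_sum = np.array([3.0, 3.0, 6.0])
        b, k = 2, 3
        raw = 12 / (b * k * (k + 1)) * (ranks_sum**2).sum() - 3 * b * (k + 1)
        corr = 1 - (2 * (2**3 - 2)) / (b * k * (k**2 - 1))
        res = friedman_test(X)
        assert res.statistic == pytest.approx(raw / corr)


class TestSmmAndT3:
    def test_single_modulus_reduces_to_two_sided_t(self):
        for q, df in [(0.5, 4.0), (2.2, 9.0), (3.7, 25.5)]:
            assert smm_sf(q, 1, df) == pytest.approx(2 * sps.t.sf(q, df), abs=1e-6)

    def test_sf_monotone_in_q_and_m(self):
        assert smm_sf(2.0, 3, 10) > smm_sf(2.5, 3, 10)
        assert smm_sf(2.0, 6, 10) > smm_sf(2.0, 3, 10)

    def test_quadrature_agrees_with_monte_carlo(self):
        p_quad = smm_sf(2.5, 6, 12.0)
        p_mc = smm_sf_mc(2.5, 6, 12.0, n_draws=200_000)
        assert p_quad == pytest.approx(p_mc, abs=0.01)

    def test_identical_groups_adjusted_p_near_one(self):
        g = [5.0, 5.1, 4.9, 5.0]
        results = dunnett_t3([g, list(g)])
        assert results[0].p_adjusted >= 0.999

    def test_adjusted_p_dominates_welch_p(self, rng):
        groups = [rng.normal(m, s, n) for m, s, n in
                  [(0, 1, 8), (0.8, 2, 10), (1.5, 0.5, 6)]]
        for pr in dunnett_t3(groups):
            assert pr.p_adjusted >= pr.p_unadjusted - 1e-12

    def test_welch_df_matches_pairwise_t_test(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(1, 3, 14)
        pr = dunnett_t3([a, b], labels=["a", "b"])[0]
        ref = t_test(a, b, "welch")
        assert pr.df == pytest.approx(ref.df)
        assert pr.statistic == pytest.approx(abs(ref.statistic))
        # m = 1: the SMM adjustment vanishes
        assert pr.p_adjusted == pytest.approx(ref.p_value, abs=1e-6)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x + 1).r == 1.0
        assert pearson_correlation(x, -x).r == -1.0

    def test_hand_evaluated_r(self):
        res = pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            n = rng.integers(4, 30)
            x = rng.normal(0, 1, n)
            y = 0.4 * x + rng.normal(0, 1, n)
            res = pearson_correlation(x, y)
            ref = sps.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_fisher_interval_contains_estimate(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        res = pearson_correlation(x, y)
        lo, hi = res.fisher_interval()
        assert lo < res.r < hi


class TestCohortReport:
    def test_identical_groups_report_null_everywhere(self, rng):
        import pandas as pd

        base = rng.normal(0.5, 0.1, 8)
        rows = []
        for gid in range(3):
            for k, v in enumerate(base):
                rows.append(
                    {"animal_id": f"g{gid}a{k}", "group_id": gid, "nmve": v,
                     "cd31_mean": 2.0 + k, "vegf_mean": 1.0 + k}
                )
        cohort = pd.DataFrame(rows)
        report = group_comparison_report(cohort, control_group=0)
        nmve_pairs = report.pairwise.query("variable == 'nmve'")
        assert (nmve_pairs["p_adjusted"] >= 0.999).all()
        assert report.omnibus["nmve"].p_value == pytest.approx(1.0)

    def test_structure_and_occlusive_exclusion(self, small_sim):
        report = group_comparison_report(small_sim.cohort, control_group=0)
        # group 5 has no nmve rows in the summary but keeps histology rows
        nmve_groups = set(
            report.summaries.query("variable == 'nmve'")["group_id"]
        )
        assert 5 not in nmve_groups
        cd31_groups = set(
            report.summaries.query("variable == 'cd31_mean'")["group_id"]
        )
        assert 5 in cd31_groups
        assert set(report.correlations["marker"]) == {"cd31_mean", "vegf_mean"}
        assert (report.correlations["n"] == 10).all()

    def test_missing_control_group_rejected(self, small_sim):
        from ceusvv.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            group_comparison_report(small_sim.cohort, control_group=9)
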