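import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bruxwear.diagnostics import (
    compare_groups,
    confusion_metrics,
    effect_size,
    fdr_adjust,
    mean_ci,
    predictive_values,
    roc_analysis,
    ttest_power,
    validation_report,
    wilcoxon_rank_sum,
)
from bruxwear.synthetic import CohortParams, simulate_cohort

from conftest import pairwise_concordance_auc


def random_cohort(rng, n_max=50):
    n_pos = int(rng.integers(2, n_max // 2))
    n_neg = int(rng.integers(2, n_max // 2))
    scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # rounding forces ties
    labels = ["SB"] * n_pos + ["non-SB"] * n_neg
    return scores, labels


class TestRoc:
    def test_perfect_separation(self):
        scores = [10, 11, 12, 1, 2, 3]
        labels = ["SB"] * 3 + ["non-SB"] * 3
        roc = roc_analysis(scores, labels)
        assert roc.auc == 1.0
        assert roc.youden_j == 1.0
        assert roc.youden_cutoff == 10  # lowest separating observed score
        assert roc.confusion == {"TP": 3, "FP": 0, "TN": 3, "FN": 0}

    def test_constant_score_auc_half(self):
        roc = roc_analysis([5.0] * 8, ["SB", "non-SB"] * 4)
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            scores, labels = random_cohort(rng)
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(
                pairwise_concordance_auc(scores, labels), abs=1e-12
            )

    def test_cutoff_itself_classifies_positive(self):
        scores = [507, 600, 100, 200]
        labels = ["SB", "SB", "non-SB", "non-SB"]
        roc = roc_analysis(scores, labels)
        assert roc.youden_cutoff == 507
        assert roc.confusion["TP"] == 2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        scores, labels = random_cohort(rng)
        base = roc_analysis(scores, labels)
        warped = roc_analysis(np.exp(scores / 2.0), labels)
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)
        assert warped.youden_j == pytest.approx(base.youden_j, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2], ["SB", "SB"])


class TestConfusionAndPredictiveValues:
    def test_study_confusion_table(self):
        m = confusion_metrics({"TP": 10, "FN": 0, "TN": 28, "FP": 7})
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(10 / 17)
        assert m["npv"] == 1.0

    def test_perfect_classifier(self):
        m = confusion_metrics({"TP": 10, "FN": 0, "TN": 35, "FP": 0})
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "ppv", "npv"))

    def test_undefined_ratio_flagged_not_raised(self):
        m = confusion_metrics({"TP": 0, "FN": 0, "TN": 5, "FP": 2})
        assert m["sensitivity"] is None
        with pytest.raises(ValueError):
            confusion_metrics({"TP": 0, "FN": 0, "TN": 0, "FP": 0})

    def test_study_predictive_values(self):
        pv = predictive_values(1.0, 0.8, 10, 35)
        assert pv["ppv"] == pytest.approx(0.588, abs=0.001)
        assert pv["npv"] == 1.0

    def test_predictive_value_arithmetic(self):
        pv = predictive_values(0.9, 0.7, 20, 80)
        assert pv["ppv"] == pytest.approx(18 / 42)
        assert pv["npv"] == pytest.approx(56 / 58)
        assert predictive_values(1.0, 1.0, 5, 5) == {"ppv": 1.0, "npv": 1.0}

    def test_agrees_with_integer_confusion_table(self):
        # whenever Se*n+ and Sp*n- are integers, both routes coincide
        for se, sp, npos, nneg in [(0.9, 0.7, 20, 80), (1.0, 0.8, 10, 35), (0.5, 0.5, 4, 4)]:
            tp = round(se * npos)
            tn = round(sp * nneg)
            m = confusion_metrics(
                {"TP": tp, "FN": npos - tp, "TN": tn, "FP": nneg - tn}
            )
            pv = predictive_values(se, sp, npos, nneg)
            assert m["ppv"] == pytest.approx(pv["ppv"])
            assert m["npv"] == pytest.approx(pv["npv"])


class TestEffectSizeAndPower:
    def test_study_effect_size(self):
        e = effect_size(1306, 913, 10, 381, 483, 35)
        assert e["cohen_d"] == pytest.approx(1.54, abs=0.005)
        assert e["hedges_g"] == pytest.approx(1.52, abs=0.005)

    def test_equal_means_zero_effect(self):
        assert effect_size(5, 2, 10, 5, 2, 10)["cohen_d"] == 0.0

    def test_hand_computed_correction(self):
        e = effect_size(10, 2, 5, 8, 2, 5)
        assert e["cohen_d"] == pytest.approx(1.0)
        assert e["hedges_g"] == pytest.approx(1.0 * (1 - 3 / 31))

    def test_power_equals_alpha_at_null(self):
        assert ttest_power(0.0, 10, 35, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_study_power_at_least_098(self):
        d = effect_size(1306, 913, 10, 381, 483, 35)["cohen_d"]
        assert ttest_power(d, 10, 35) >= 0.98

    def test_power_matches_monte_carlo(self):
        d, n1, n2 = 1.0, 10, 35
        analytic = ttest_power(d, n1, n2)
        rng = np.random.default_rng(99)
        reps = 20_000
        x = rng.normal(d, 1.0, size=(reps, n1))
        y = rng.normal(0.0, 1.0, size=(reps, n2))
        sp = np.sqrt(
            ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1))
            / (n1 + n2 - 2)
        )
        t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(1 / n1 + 1 / n2))
        tcrit = stats.t.ppf(0.975, n1 + n2 - 2)
        assert analytic == pytest.approx((np.abs(t) > tcrit).mean(), abs=0.02)

    def test_power_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        ref = TTestIndPower().power(1.0, nobs1=10, ratio=3.5, alpha=0.05)
        assert ttest_power(1.0, 10, 35) == pytest.approx(ref, abs=1e-6)

    @given(
        d=st.floats(0.1, 2.5), n1=st.integers(5, 30), n2=st.integers(5, 30),
        dd=st.floats(0.05, 1.0), dn=st.integers(1, 10),
    )
    @settings(derandomize=True, max_examples=40)
    def test_power_monotone_in_effect_and_n(self, d, n1, n2, dd, dn):
        base = ttest_power(d, n1, n2)
        assert ttest_power(d + dd, n1, n2) >= base - 1e-12
        assert ttest_power(d, n1 + dn, n2) >= base - 1e-12
        assert ttest_power(d, n1, n2 + dn) >= base - 1e-12


class TestMeanCi:
    def test_study_intervals_to_printed_integers(self):
        lo, hi = mean_ci(1306, 913, 10)
        assert (round(lo), round(hi)) == (653, 1959)
        assert lo == pytest.approx(652.9, abs=0.05)
        lo, hi = mean_ci(381, 483, 35)
        assert (round(lo), round(hi)) == (215, 547)

    def test_zero_sd_collapses(self):
        assert mean_ci(5.0, 0.0, 10) == (5.0, 5.0)


class TestGroupComparisons:
    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_raw == 1.0

    def test_exact_p_small_example(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.test_used == "wilcoxon_exact"
        assert res.p_raw == pytest.approx(0.1)

    def test_exact_matches_full_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            pooled = np.round(rng.normal(size=n1 + n2), 1)
            x, y = pooled[:n1], pooled[n1:]
            got = wilcoxon_rank_sum(x, y).p_raw
            ranks = stats.rankdata(pooled)
            obs = ranks[:n1].sum()
            mu = n1 * (len(pooled) + 1) / 2
            count = 0
            combos = list(itertools.combinations(range(len(pooled)), n1))
            for idx in combos:
                if abs(ranks[list(idx)].sum() - mu) >= abs(obs - mu) - 1e-9:
                    count += 1
            assert got == pytest.approx(count / len(combos), abs=1e-12)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 1, 20)
        y = rng.normal(0.0, 1, 30)
        got = wilcoxon_rank_sum(x, y)
        assert got.test_used == "wilcoxon_normal"
        ref = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert got.p_raw == pytest.approx(ref, abs=1e-6)

    def test_auto_routes_by_shapiro(self):
        rng = np.random.default_rng(11)
        near_normal = compare_groups(rng.normal(0, 1, 20), rng.normal(1, 1, 20))
        assert near_normal.test_used == "welch_t"
        assert near_normal.df is not None and near_normal.df < 38  # fractional Welch df
        skewed = compare_groups(rng.gamma(0.6, 600, 35), rng.gamma(0.6, 600, 35))
        assert skewed.test_used.startswith("wilcoxon")

    def test_welch_df_fractional_on_study_like_data(self):
        rng = np.random.default_rng(8)
        x = rng.normal(1306, 913, 10)
        y = rng.normal(381, 483, 35)
        res = compare_groups(x, y, method="welch_t")
        assert res.df < 43  # below the pooled df, as Welch-Satterthwaite requires
        assert res.df != int(res.df)


class TestFdr:
    def test_hand_computed_step_up(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
        # sorted: 0.005, 0.03, 0.04 -> 0.015, min(0.045, 0.04), 0.04
        adj = fdr_adjust([0.005, 0.04, 0.03])
        assert np.allclose(adj, [0.015, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=50)
    def test_dominance_and_idempotence(self, pvals):
        adj = fdr_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestValidationReport:
    def test_large_cohort_recovers_generating_conditions(self):
        cohort = simulate_cohort(CohortParams(n_sb=4000, n_nsb=4000, seed=17))
        report = validation_report(cohort)
        assert report.mean_ratio == pytest.approx(1306 / 381, rel=0.05)
        assert 0.75 < report.roc.auc < 0.9

    def test_perfectly_separated_toy_cohort(self):
        cohort = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "group": ["SB"] * 3 + ["non-SB"] * 3,
                "pixel_score": [900, 1000, 1100, 100, 200, 300],
            }
        )
        report = validation_report(cohort)
        assert report.roc.auc == 1.0
        assert report.metrics["sensitivity"] == 1.0
        assert report.metrics["specificity"] == 1.0
        assert report.predictive == {"ppv": 1.0, "npv": 1.0}

    def test_deterministic_given_seed(self):
        a = validation_report(simulate_cohort(CohortParams(seed=4))).to_dict()
        b = validation_report(simulate_cohort(CohortParams(seed=4))).to_dict()
        assert a == b

    def test_fdr_applied_across_variables(self):
        cohort = simulate_cohort(CohortParams(seed=9))
        rng = np.random.default_rng(1)
        cohort["noise"] = rng.normal(size=len(cohort))
        report = validation_report(cohort, extra_variables=["noise"])
        for t in report.tests.values():
            assert t.p_adjusted >= t.p_raw - 1e-12

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="group"):
            validation_report(pd.DataFrame({"pixel_score": [1.0, 2.0]}))
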