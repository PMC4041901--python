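"""Diagnostic metrics, criteria combination, ROC/DeLong, McNemar, Cochran's Q."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from t1topo.diagnostics import (
    DiagnosticSummary,
    bayes_predictive_values,
    cochran_q,
    combine_criteria,
    counts_from_rates,
    delong_compare,
    mcnemar_test,
    roc_auc,
    summarize_criterion,
)

from oracles import auc_pair_counting, cochran_q_oracle, delong_oracle


class TestSummaries:
    def test_perfect_classifier(self):
        truth = pd.Series([True] * 5 + [False] * 5)
        s = summarize_criterion(truth.copy(), truth)
        assert (s.sensitivity, s.specificity, s.accuracy, s.ppv, s.npv) == (
            100.0, 100.0, 100.0, 100.0, 100.0
        )

    def test_t1_row_counts_reconstruct_printed_metrics(self):
        """SN 90 / SP 88 on 60 patients and 50 controls -> 89 / 90 / 88."""
        s = counts_from_rates(90.0, 88.0, 60, 50)
        assert (s.tp, s.fn, s.tn, s.fp) == (54, 6, 44, 6)
        r = s.rounded()
        assert (r["accuracy"], r["ppv"], r["npv"]) == (89.0, 90.0, 88.0)

    def test_dark_blood_t2_row_predictive_values(self):
        """SN 48 / SP 86 on 60/50 -> PPV 81, NPV 58."""
        s = counts_from_rates(48.0, 86.0, 60, 50)
        r = s.rounded()
        assert (r["ppv"], r["npv"]) == (81.0, 58.0)

    def test_non_evaluable_subjects_dropped(self):
        decisions = pd.Series([True, False, np.nan, True], dtype="object")
        truth = pd.Series([True, False, False, False])
        s = summarize_criterion(decisions, truth)
        assert s.n_controls == 2  # NaN control dropped from the arm

    def test_zero_arm_reports_missing(self):
        s = DiagnosticSummary(tp=3, fp=0, tn=0, fn=1)
        assert np.isnan(s.specificity)

    @pytest.mark.parametrize("seed", range(5))
    def test_bayes_identity_on_random_tables(self, seed):
        """PPV/NPV recomputed from SN, SP and class sizes equal count-based values."""
        rng = np.random.default_rng(seed)
        truth = pd.Series(rng.random(40) < 0.5)
        decisions = pd.Series(rng.random(40) < 0.5)
        if truth.all() or not truth.any():
            truth.iloc[0] = ~truth.iloc[0]
        s = summarize_criterion(decisions, truth)
        ppv, npv = bayes_predictive_values(
            s.sensitivity, s.specificity, s.n_patients, s.n_controls
        )
        assert ppv == pytest.approx(s.ppv) and npv == pytest.approx(s.npv)


class TestCombinations:
    def test_or_with_itself_is_identity(self):
        d = pd.Series([True, False, True])
        combined = combine_criteria(pd.DataFrame({"a": d, "b": d}), k=1)
        assert combined.tolist() == d.tolist()

    def test_any_two_of_three_matches_majority_enumeration(self):
        patterns = pd.DataFrame(
            [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)],
            columns=list("abc"), dtype=bool,
        )
        combined = combine_criteria(patterns, k=2)
        brute = patterns.sum(axis=1) >= 2
        assert combined.tolist() == brute.tolist()

    @pytest.mark.parametrize("seed", range(5))
    def test_or_raises_sensitivity_and_raises_specificity(self, seed):
        rng = np.random.default_rng(100 + seed)
        truth = pd.Series(np.r_[np.ones(20, bool), np.zeros(20, bool)])
        d = pd.DataFrame(rng.random((40, 2)) < 0.5, columns=["a", "b"])
        sn = {c: summarize_criterion(d[c], truth).sensitivity for c in d}
        sp = {c: summarize_criterion(d[c], truth).specificity for c in d}
        s_or = summarize_criterion(combine_criteria(d, 1), truth)
        s_and = summarize_criterion(combine_criteria(d, 2), truth)
        assert s_or.sensitivity >= max(sn.values())
        assert s_and.specificity >= max(sp.values())

    def test_invalid_k_rejected(self):
        d = pd.DataFrame({"a": [True], "b": [False]})
        for k in (0, 3):
            with pytest.raises(ValueError):
                combine_criteria(d, k)

    def test_incomplete_subjects_dropped_from_combination(self):
        d = pd.DataFrame({"a": [True, True], "b": [True, np.nan]}, dtype="object")
        assert len(combine_criteria(d, 1)) == 1


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75  # swapped middle labels

    def test_tied_cross_class_pair_contributes_half(self):
        # one tied cross-class pair among 2x2 subjects: AUC = (3 + 0.5)/4
        assert roc_auc([1.0, 2.0, 2.0, 3.0], [0, 0, 1, 1]) == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 10, n).astype(float)  # integer scores force ties
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        assert roc_auc(scores, truth) == pytest.approx(auc_pair_counting(scores, truth))

    def test_constant_scores_degenerate_to_half(self):
        assert roc_auc([1.0, 1.0, 1.0], [1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_scores_give_zero_z_unit_p(self):
        scores = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        truth = np.array([1, 0, 1, 0, 1, 0], bool)
        auc_a, auc_b, z, p = delong_compare(scores, scores, truth)
        assert auc_a == auc_b and z == 0.0 and p == 1.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(99)
        truth = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        a = rng.normal(truth.astype(float), 1.0)
        b = rng.normal(truth.astype(float), 2.0)
        auc_a, auc_b, z, _ = delong_compare(a, b, truth)
        oa, ob, oz = delong_oracle(a, b, truth)
        assert auc_a == pytest.approx(oa) and auc_b == pytest.approx(ob)
        assert z == pytest.approx(oz)

    def test_sign_of_z_matches_auc_ordering(self):
        rng = np.random.default_rng(5)
        truth = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        strong = rng.normal(2 * truth.astype(float), 0.5)
        weak = rng.normal(0.3 * truth.astype(float), 1.5)
        auc_a, auc_b, z, p = delong_compare(strong, weak, truth)
        assert auc_a > auc_b and z > 0 and p < 0.05

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1.0, 2.0], [1.0], [True, False])


class TestMcNemar:
    def test_exact_p_for_five_one_discordance(self):
        a = np.r_[np.ones(5, bool), np.zeros(1, bool), np.ones(4, bool)]
        b = np.r_[np.zeros(5, bool), np.ones(1, bool), np.ones(4, bool)]
        assert mcnemar_test(a, b) == pytest.approx(0.21875)

    def test_equal_discordance_capped_at_one(self):
        a = np.array([1, 1, 0, 0, 1, 0], bool)
        b = np.array([0, 0, 1, 1, 1, 0], bool)
        assert mcnemar_test(a, b) == 1.0

    def test_no_discordance_gives_unit_p(self):
        a = np.array([1, 0, 1], bool)
        assert mcnemar_test(a, a) == 1.0

    def test_exact_and_chisquare_branches_agree_for_large_n(self):
        rng = np.random.default_rng(11)
        a = rng.random(400) < 0.5
        b = a.copy()
        flip = rng.random(400) < 0.25
        b[flip] = ~b[flip]
        exact = mcnemar_test(a, b, exact_max_discordant=10**6)
        approx = mcnemar_test(a, b, exact_max_discordant=0)
        assert abs(exact - approx) < 0.01

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        a = np.r_[np.ones(12, bool), np.zeros(8, bool)]
        b = np.r_[np.ones(5, bool), np.zeros(10, bool), np.ones(5, bool)]
        table = [[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]]
        expected = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar_test(a, b) == pytest.approx(expected, abs=1e-9)


class TestCochranQ:
    def test_identical_columns_give_zero_q(self):
        d = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0], "c": [1, 0, 1, 0]})
        q, df, p = cochran_q(d)
        assert q == 0.0 and df == 2 and p == 1.0

    def test_k_two_reduces_to_mcnemar_chisquare_without_correction(self):
        rng = np.random.default_rng(17)
        a = rng.random(60) < 0.6
        b = rng.random(60) < 0.4
        q, df, _ = cochran_q(pd.DataFrame({"a": a, "b": b}))
        n01 = int((a & ~b).sum())
        n10 = int((~a & b).sum())
        assert df == 1
        assert q == pytest.approx((n01 - n10) ** 2 / (n01 + n10))

    def test_matches_direct_formula_and_statsmodels(self):
        from statsmodels.stats.contingency_tables import cochrans_q

        rng = np.random.default_rng(23)
        x = (rng.random((20, 3)) < 0.5).astype(int)
        q, df, p = cochran_q(pd.DataFrame(x))
        assert q == pytest.approx(cochran_q_oracle(x))
        sm = cochrans_q(x)
        assert q == pytest.approx(sm.statistic) and p == pytest.approx(sm.pvalue)

    def test_single_criterion_rejected(self):
        with pytest.raises(ValueError):
            cochran_q(pd.DataFrame({"a": [1, 0]}))
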