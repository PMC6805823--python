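"""Diagnostic statistics: 2x2 metrics, CIs, LRs, Bayes, ROC, tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from cadscore import (ConfusionMatrix, anova_test, chi_square_test, confusion_matrix,
                      delong_paired_test, diagnostic_summary, exact_proportion,
                      hanley_unpaired_test, likelihood_ratios, pearson_test,
                      post_test_probability, roc_auc, stratified_performance, t_test)
from cadscore.stats import hanley_mcneil_se


def auc_pair_counting(scores, labels):
    """O(n^2) oracle: fraction of (event, non-event) pairs ranked
    correctly, ties half credit."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_hand_tally(self):
        pred = [1, 1, 0, 0, 1, 0]
        truth = [1, 0, 1, 0, 1, 0]
        cm = confusion_matrix(pred, truth)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 1, 2, 1)

    def test_all_correct_no_errors(self):
        cm = confusion_matrix([1, 0, 1], [1, 0, 1])
        assert cm.fp == 0 and cm.fn == 0

    def test_complement_predictions(self):
        cm = confusion_matrix([0, 1, 0], [1, 0, 1])
        assert cm.tp == 0 and cm.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 0], [1, 0, 1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=1, fn=0)


class TestDiagnosticSummary:
    def test_perfect_test_all_100(self):
        s = diagnostic_summary(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0))
        assert (s.sensitivity.pct, s.specificity.pct, s.ppv.pct, s.npv.pct) == \
            (100.0, 100.0, 100.0, 100.0)

    def test_undefined_metric_is_nan_not_fatal(self):
        s = diagnostic_summary(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(s.ppv.value)
        assert s.npv.value == 0.5

    def test_ci_contains_point_estimate(self):
        p = exact_proportion(30, 100)
        assert p.ci_low <= p.value <= p.ci_high


class TestLikelihoodRatios:
    def test_boundary_cases(self):
        assert likelihood_ratios(1.0, 0.5) == (2.0, 0.0)
        with pytest.warns(UserWarning):
            plr, _ = likelihood_ratios(0.9, 1.0)
        assert np.isinf(plr)
        with pytest.warns(UserWarning):
            _, nlr = likelihood_ratios(0.9, 0.0)
        assert np.isnan(nlr)

    def test_lr_of_one_preserves_prevalence(self):
        assert post_test_probability(0.3, 1.0) == pytest.approx(0.3, abs=1e-12)

    def test_boundary_prevalence_rejected(self):
        for prev in (0.0, 1.0):
            with pytest.raises(ValueError):
                post_test_probability(prev, 2.0)


@given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500))
def test_bayes_identity_on_random_confusion_matrices(tp, fp, tn, fn):
    """post(prev, PLR) = PPV and 1 - post(prev, NLR) = NPV, exactly."""
    s = diagnostic_summary(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
    prev = (tp + fn) / (tp + fp + tn + fn)
    assert post_test_probability(prev, s.plr) == pytest.approx(s.ppv.value, abs=1e-12)
    assert 1 - post_test_probability(prev, s.nlr) == pytest.approx(s.npv.value, abs=1e-12)


class TestROC:
    def test_perfect_separation_auc_one(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=4000)
        y = rng.random(4000) < 0.3
        assert roc_auc(s, y).auc == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(8, 21)
            s = rng.integers(0, 6, n).astype(float)  # force ties
            y = np.zeros(n, bool)
            y[rng.choice(n, max(1, n // 3), replace=False)] = True
            if y.all() or not y.any():
                continue
            assert roc_auc(s, y).auc == pytest.approx(auc_pair_counting(s, y), abs=1e-12)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.4
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.4
        assert roc_auc(np.exp(s), y).auc == pytest.approx(roc_auc(s, y).auc, abs=1e-12)

    def test_curve_monotone_and_area_consistent(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=200)
        y = rng.random(200) < 0.3
        r = roc_auc(s + (y * 0.8), y)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_scores_p_one(self):
        s = np.arange(40.0)
        y = np.r_[np.zeros(20), np.ones(20)].astype(bool)
        with pytest.warns(UserWarning):
            res = delong_paired_test(s, s, y)
        assert res.p_value == 1.0

    def test_monotone_transform_zero_difference(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=80)
        y = rng.random(80) < 0.4
        res = delong_paired_test(s, np.tanh(s), y)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(6)
        n = 120
        latent = rng.normal(size=n)
        y = rng.random(n) < 1 / (1 + np.exp(-latent))
        if y.all() or not y.any():  # pragma: no cover
            pytest.skip("degenerate draw")
        a = latent + rng.normal(0, 1.0, n)
        b = latent + rng.normal(0, 1.6, n)
        res = delong_paired_test(a, b, y)
        # bootstrap the AUC difference, normal-approximation p
        diffs = np.empty(4000)
        idx_all = np.arange(n)
        for i in range(4000):
            idx = rng.choice(idx_all, n, replace=True)
            yy = y[idx]
            if yy.all() or not yy.any():
                idx = idx_all
                yy = y
            diffs[i] = (roc_auc(a[idx], yy).auc - roc_auc(b[idx], yy).auc)
        obs = roc_auc(a, y).auc - roc_auc(b, y).auc
        z = obs / diffs.std(ddof=1)
        p_boot = 2 * sps.norm.sf(abs(z))
        assert res.p_value == pytest.approx(p_boot, abs=0.02)


class TestHanley:
    def test_identical_groups_p_one(self):
        res = hanley_unpaired_test(0.7, 50, 100, 0.7, 50, 100)
        assert res.p_value == 1.0

    def test_closed_form_at_auc_half(self):
        # Q1 = Q2 = 1/3 when A = 0.5
        npos, nneg = 30, 70
        expected = np.sqrt((0.25 + (npos - 1) * (1 / 3 - 0.25)
                            + (nneg - 1) * (1 / 3 - 0.25)) / (npos * nneg))
        assert hanley_mcneil_se(0.5, npos, nneg) == pytest.approx(expected, abs=1e-15)

    def test_larger_n_shrinks_p(self):
        p_small = hanley_unpaired_test(0.75, 30, 60, 0.70, 30, 60).p_value
        p_large = hanley_unpaired_test(0.75, 300, 600, 0.70, 300, 600).p_value
        assert p_large < p_small

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            hanley_unpaired_test(0.7, 1, 100, 0.7, 50, 100)


class TestBasicTests:
    def test_chi_square_hand_computation(self):
        # 2x2 shortcut: X2 = n(ad-bc)^2 / (r1 r2 c1 c2)
        res = chi_square_test([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(60 * (100 - 400) ** 2 / 810000, abs=1e-12)

    def test_chi_square_identical_proportions(self):
        res = chi_square_test([[10, 90], [20, 180]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])

    def test_t_identical_groups_zero(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_anova_hand_computed_f(self):
        # groups (1,2,3), (2,3,4), (3,4,5): MSB = 3, MSW = 1 -> F = 3
        res = anova_test([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert res.statistic == pytest.approx(3.0, abs=1e-12)
        assert res.p_value == pytest.approx(sps.f.sf(3.0, 2, 6), abs=1e-12)

    def test_pearson_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson_test(x, x).statistic == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestStratified:
    def _cohort(self):
        import pandas as pd
        return pd.DataFrame({
            "disease_level": ["significant_cad", "non_cad"] * 10,
            "cad_score": [60, 10, 70, 15, 30, 5, 80, 25, 10, 18] * 2,
            "stratum": ["a"] * 10 + ["b"] * 10,
        })

    def test_constant_stratifier_equals_pooled(self):
        df = self._cohort()
        df["stratum"] = "all"
        out = stratified_performance(df, "stratum")
        pooled_truth = (df["disease_level"] == "significant_cad").to_numpy()
        pooled = diagnostic_summary(
            confusion_matrix(df["cad_score"].to_numpy() > 20, pooled_truth))
        assert out["all"]["summary"].as_dict() == pooled.as_dict()

    def test_stratum_without_events_omits_auc(self):
        import pandas as pd
        df = pd.DataFrame({
            "disease_level": ["non_cad"] * 6 + ["significant_cad", "non_cad"] * 3,
            "cad_score": [10, 30, 15, 25, 5, 40] + [60, 10] * 3,
            "stratum": ["noevents"] * 6 + ["mixed"] * 6,
        })
        out = stratified_performance(df, "stratum")
        assert out["noevents"]["roc"] is None
        assert not np.isnan(out["noevents"]["summary"].specificity.value)
        assert out["mixed"]["roc"] is not None

    def test_two_strata_hand_tally(self):
        out = stratified_performance(self._cohort(), "stratum")
        # per stratum: events have scores 60,70,30,80,10 -> 4 of 5 above 20
        for key in ("a", "b"):
            assert out[key]["summary"].sensitivity.value == pytest.approx(0.8)
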