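"""Group tests, LDA, ROC and survival: closed-form oracles + power checks."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from qustex.stats import (
    PooledLDA,
    classify_and_score,
    compare_groups,
    fit_lda,
    km_estimate,
    ks_normality,
    logrank,
    roc_auc,
)


class TestKSNormality:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(0).normal(size=200)
        passed, stat, p = ks_normality(x)
        assert passed

    def test_two_point_mass_fails(self):
        x = np.tile([0.0, 1.0], 100)
        passed, stat, p = ks_normality(x)
        assert not passed
        assert stat > 0.25  # KS distance of a two-point mass vs normal

    def test_constant_vector_fails_explicitly(self):
        assert ks_normality(np.full(10, 3.0))[0] is False

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestCompareGroups:
    def test_identical_normal_groups_t_branch(self):
        x = np.random.default_rng(1).normal(size=30)
        c = compare_groups(x, x)
        assert c.test_used == "t-test"
        assert c.statistic == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)

    def test_identical_bimodal_groups_ks_branch(self):
        x = np.tile([0.0, 10.0], 15)
        c = compare_groups(x, x)
        assert c.test_used == "ks"
        assert c.p_value == pytest.approx(1.0)

    def test_power_at_large_effect(self):
        # N(0,1) vs N(3,1) with n = 15/5: reject in >= 90% of 100 replicates
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(100):
            a = rng.normal(0.0, 1.0, 15)
            b = rng.normal(3.0, 1.0, 5)
            rejections += compare_groups(a, b).p_value < 0.05
        assert rejections >= 90

    def test_ks_statistic_matches_ecdf_oracle(self):
        a = np.array([1.0, 3.0, 5.0, 7.0])
        b = np.array([2.0, 2.5, 6.0])

        def ecdf_sup(a, b):
            grid = np.concatenate([a, b])
            fa = np.array([(a <= g).mean() for g in grid])
            fb = np.array([(b <= g).mean() for g in grid])
            return np.max(np.abs(fa - fb))

        assert sps.ks_2samp(a, b, method="exact").statistic == pytest.approx(ecdf_sup(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestPooledLDA:
    def test_perfectly_separated_1d(self):
        X = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array(["responder"] * 3 + ["non-responder"] * 3)
        model = fit_lda(X, y)
        assert (model.predict(X) == y).all()
        # decision boundary between 2 and 10
        assert model.decision_function([[2.0]])[0] < 0 < model.decision_function([[10.0]])[0]

    def test_coefficients_match_closed_form_solve(self):
        rng = np.random.default_rng(3)
        X0 = rng.normal(0.0, 1.0, size=(40, 2))
        X1 = rng.normal([2.0, -1.0], 1.0, size=(25, 2))
        X = np.vstack([X0, X1])
        y = np.array(["responder"] * 40 + ["non-responder"] * 25)
        model = fit_lda(X, y)
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (65 - 2)
        w = np.linalg.solve(S, mu1 - mu0)
        assert np.allclose(model.coef_, w, atol=1e-8)

    def test_direction_agrees_with_sklearn(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1.2, 1, (30, 3))])
        y = np.array(["responder"] * 30 + ["non-responder"] * 30)
        ours = fit_lda(X, y).coef_
        sk = LinearDiscriminantAnalysis().fit(X, y).coef_.ravel()
        # sklearn orders classes alphabetically: non-responder is class 0, so
        # its coefficient vector points the other way
        cos = ours @ sk / (np.linalg.norm(ours) * np.linalg.norm(sk))
        assert abs(cos) > 0.99

    def test_singular_covariance_ridge_fallback(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [6.0, 6.0]])
        y = np.array(["responder"] * 3 + ["non-responder"] * 2)
        model = PooledLDA(ridge=1e-6).fit(X, y)
        assert np.all(np.isfinite(model.coef_))
        assert model.ridge_used_ > 0
        with pytest.raises(ValueError, match="singular"):
            PooledLDA(ridge=None).fit(X, y)


class TestClassifyAndScore:
    def test_perfect_separation_scores_100(self):
        X = np.array([0.0, 0.5, 1.0, 9.0, 9.5, 10.0])
        y = np.array(["responder"] * 3 + ["non-responder"] * 3)
        res = classify_and_score(X, y, eval_mode="loo")
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.auc == 1.0

    def test_uninformative_features_predict_majority(self):
        X = np.zeros(20)  # no signal at all: the prior decides
        y = np.array(["responder"] * 15 + ["non-responder"] * 5)
        res = classify_and_score(X, y, eval_mode="resubstitution")
        # all predicted responder: sensitivity 0, specificity 100
        assert res.sensitivity == 0.0
        assert res.specificity == 100.0

    def test_sensitivity_plus_fnr_is_100(self):
        rng = np.random.default_rng(6)
        X = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 5)])
        y = np.array(["responder"] * 15 + ["non-responder"] * 5)
        res = classify_and_score(X, y, eval_mode="loo")
        fn = np.sum((res.predicted != "non-responder") & (y == "non-responder"))
        fnr = 100.0 * fn / 5
        assert res.sensitivity + fnr == pytest.approx(100.0)


class TestROC:
    def test_perfect_ranking(self):
        y = np.array(["responder"] * 4 + ["non-responder"] * 4)
        *_, auc = roc_auc(np.r_[np.zeros(4), np.ones(4)], y)
        assert auc == 1.0

    def test_all_scores_equal_gives_half(self):
        y = np.array(["responder"] * 4 + ["non-responder"] * 4)
        *_, auc = roc_auc(np.zeros(8), y)
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney_identity(self):
        rng = np.random.default_rng(8)
        scores = np.round(rng.normal(size=40), 1)  # ties included
        y = np.array(["non-responder" if v else "responder" for v in rng.integers(0, 2, 40)])
        *_, auc = roc_auc(scores, y)
        u = sps.mannwhitneyu(scores[y == "non-responder"], scores[y == "responder"]).statistic
        n1, n2 = (y == "non-responder").sum(), (y == "responder").sum()
        assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        y = np.array(["non-responder" if v else "responder" for v in rng.integers(0, 2, 30)])
        *_, a1 = roc_auc(scores, y)
        *_, a2 = roc_auc(np.exp(scores) + 3.0, y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], np.array(["responder", "responder"]))


def _logrank_oracle(times, events, groups):
    """Exhaustive risk-table computation of the two-group log-rank statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    gnames = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == gnames[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == gnames[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, sps.chi2.sf(chi2, 1)


class TestSurvival:
    def test_no_events_survival_stays_one(self):
        curves = km_estimate([5.0, 8.0, 12.0], [False] * 3, ["a"] * 3)
        assert np.all(curves["a"].survival == 1.0)

    def test_hand_product_limit(self):
        curves = km_estimate([1.0, 2.0, 3.0], [True] * 3, ["a"] * 3)
        c = curves["a"]
        lookup = dict(zip(c.times, c.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10.0, 40)
        curves = km_estimate(t, np.ones(40, bool), ["a"] * 40)
        c = curves["a"]
        for ti, si in zip(c.times, c.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_event_processed_before_censoring_at_ties(self):
        # a subject censored at t stays in the risk set for the event at t
        curves = km_estimate([2.0, 2.0, 4.0], [True, False, True], ["a"] * 3)
        c = curves["a"]
        lookup = dict(zip(c.times, c.survival))
        assert lookup[2.0] == pytest.approx(2 / 3)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True], ["a", "a"])

    def test_identical_groups_give_null_logrank(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [True] * 6
        g = ["a"] * 3 + ["b"] * 3
        res = logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_risk_table_oracle_on_toy_cohort(self):
        t = [2.0, 4.0, 5.0, 3.0, 6.0, 9.0]
        e = [True, True, False, True, True, True]
        g = ["a", "a", "a", "b", "b", "b"]
        res = logrank(t, e, g)
        chi2, p = _logrank_oracle(t, e, g)
        assert res.statistic == pytest.approx(chi2, rel=1e-6)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank([1.0, 2.0], [False, False], ["a", "b"])

    def test_power_at_hazard_ratio_four(self):
        # exponential groups with hazard ratio 4 and n = 15/5 carry a true
        # log-rank power of ~0.72 uncensored (Schoenfeld: z = log(4) *
        # sqrt(20 * 0.75 * 0.25) = 2.68); over 100 replicates the rejection
        # count should sit well above half and below certainty
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(100):
            t1 = rng.exponential(48.0 / np.log(2.0), 15)
            t2 = rng.exponential(12.0 / np.log(2.0), 5)
            t = np.concatenate([t1, t2])
            e = np.ones(20, bool)
            g = ["r"] * 15 + ["n"] * 5
            rejections += logrank(t, e, g).p_value < 0.05
        assert 60 <= rejections <= 90
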