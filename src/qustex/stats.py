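"""Group comparison, LDA classification, ROC and recurrence-free survival.

The analysis asks three questions of the delta biomarkers:

1. do responders and non-responders differ? — a pooled-variance t-test when
   both groups pass a one-sample KS normality check at alpha = 0.05,
   otherwise a two-sample (exact small-sample) KS test;
2. how well does a biomarker (or combination) detect non-responders? —
   pooled-covariance linear discriminant analysis with leave-one-out
   evaluation, reporting sensitivity/specificity on the non-responder
   (positive) class and the ROC area of the discriminant scores;
3. do the predicted groups differ in recurrence-free survival? —
   Kaplan-Meier curves compared with a log-rank test.

The KS normality check standardises with the estimated mean/SD (the
Lilliefors caveat applies: the gate is conservative, i.e. it errs toward
the distribution-free two-sample test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "non-responder"
NEGATIVE_CLASS = "responder"


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    biomarker: str
    visit: str
    test_used: str  # "t-test" | "ks"
    statistic: float
    p_value: float
    mean_responder: float
    se_responder: float
    mean_nonresponder: float
    se_nonresponder: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def ks_normality(values, alpha: float = 0.05):
    """One-sample KS test of standardised values against N(0, 1).

    Returns ``(passed, statistic, p_value)``; a degenerate (zero-SD) sample
    fails explicitly.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return False, 1.0, 0.0
    z = (x - x.mean()) / sd
    stat, p = sps.kstest(z, "norm")
    return bool(p > alpha), float(stat), float(p)


def compare_groups(
    responder_values, nonresponder_values, biomarker: str = "", visit: str = ""
) -> GroupComparison:
    """Normality-gated two-group comparison (pooled t-test or two-sample KS)."""
    a = np.asarray(responder_values, dtype=float)
    b = np.asarray(nonresponder_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 defined values")
    try:
        normal = ks_normality(a)[0] and ks_normality(b)[0]
    except ValueError:
        normal = False
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t-test"
    else:
        method = "exact" if max(a.size, b.size) <= 25 else "auto"
        res = sps.ks_2samp(a, b, method=method)
        stat, p = res.statistic, res.pvalue
        test = "ks"
    return GroupComparison(
        biomarker=biomarker,
        visit=visit,
        test_used=test,
        statistic=float(stat),
        p_value=float(min(max(p, 0.0), 1.0)),
        mean_responder=float(a.mean()),
        se_responder=float(a.std(ddof=1) / np.sqrt(a.size)),
        mean_nonresponder=float(b.mean()),
        se_nonresponder=float(b.std(ddof=1) / np.sqrt(b.size)),
    )


# ---------------------------------------------------------------------------
# linear discriminant classification
# ---------------------------------------------------------------------------


class PooledLDA(BaseEstimator, ClassifierMixin):
    """Two-class Gaussian equal-covariance (Fisher) linear discriminant.

    ``w = Sigma_pooled^-1 (mu_pos - mu_neg)``, threshold at equal posterior
    with empirical priors.  A ridge ``eps * mean(diag) * I`` is added when
    the pooled covariance is singular (``ridge=None`` turns the fallback
    off and raises instead).

    Attributes (after ``fit``): ``coef_``, ``intercept_``, ``classes_``,
    ``means_``, ``covariance_``, ``ridge_used_``.
    """

    def __init__(self, positive_class: str = POSITIVE_CLASS, ridge: float | None = 1e-6):
        self.positive_class = positive_class
        self.ridge = ridge

    def fit(self, X, y) -> "PooledLDA":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(y)) > 1:
            X = X.T
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("PooledLDA is a two-class discriminant")
        if self.positive_class in classes:
            neg = classes[classes != self.positive_class][0]
            pos = self.positive_class
        else:  # generic labels: highest sorts last
            neg, pos = classes[0], classes[1]
        self.classes_ = np.array([neg, pos])
        Xn, Xp = X[y == neg], X[y == pos]
        if len(Xn) < 1 or len(Xp) < 1:
            raise ValueError("each class needs at least one sample")
        mu_n, mu_p = Xn.mean(axis=0), Xp.mean(axis=0)
        n = len(X)
        scatter = np.zeros((X.shape[1], X.shape[1]))
        for Xc, mu in ((Xn, mu_n), (Xp, mu_p)):
            d = Xc - mu
            scatter += d.T @ d
        dof = max(n - 2, 1)
        cov = scatter / dof
        self.ridge_used_ = 0.0
        try:
            w = np.linalg.solve(cov, mu_p - mu_n)
            if not np.all(np.isfinite(w)) or np.linalg.cond(cov) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            if self.ridge is None:
                raise ValueError(
                    "pooled within-class covariance is singular; enable the ridge fallback"
                ) from None
            eps = self.ridge * max(np.trace(cov) / cov.shape[0], 1.0)
            logger.warning("singular pooled covariance; applying ridge %.3g", eps)
            w = np.linalg.solve(cov + eps * np.eye(cov.shape[0]), mu_p - mu_n)
            self.ridge_used_ = float(eps)
        prior_p = len(Xp) / n
        threshold = float(w @ (mu_n + mu_p) / 2.0 - np.log(prior_p / (1.0 - prior_p)))
        self.coef_ = w
        self.intercept_ = -threshold
        self.means_ = np.vstack([mu_n, mu_p])
        self.covariance_ = cov
        return self

    def _as_matrix(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = len(self.coef_)
        if X.ndim == 1:
            return X.reshape(-1, 1) if p == 1 else X.reshape(1, -1)
        if X.shape[1] != p and X.shape[0] == p:
            return X.T
        return X

    def decision_function(self, X) -> np.ndarray:
        return self._as_matrix(X) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def fit_lda(features, labels, positive_class: str = POSITIVE_CLASS, ridge: float | None = 1e-6):
    """Fit the pooled-covariance discriminant; returns the fitted estimator."""
    return PooledLDA(positive_class=positive_class, ridge=ridge).fit(features, labels)


@dataclass
class ClassificationResult:
    biomarkers: tuple
    visit: str
    eval_mode: str  # "loo" | "resubstitution"
    sensitivity: float  # %, positive class = non-responder
    specificity: float  # %
    auc: float
    p_value: float  # group comparison of the discriminant scores
    scores: np.ndarray = field(repr=False, default=None)
    predicted: np.ndarray = field(repr=False, default=None)
    coefficients: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if not 0.0 <= v <= 100.0:
                raise ValueError("sensitivity/specificity must be percentages in [0, 100]")


def roc_auc(scores, labels, positive_class: str = POSITIVE_CLASS):
    """ROC by threshold sweep over the unique scores; AUC by trapezoid.

    Ties receive half credit (the trapezoid through a tied block), making the
    AUC equal to the Mann-Whitney U statistic divided by ``n_pos * n_neg``.
    Returns ``(fpr, tpr, thresholds, auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s, p = scores[order], pos[order]
    # cut after each block of tied scores
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(p)[distinct]
    fp = np.cumsum(~p)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def classify_and_score(
    features,
    labels,
    biomarkers=("",),
    visit: str = "",
    positive_class: str = POSITIVE_CLASS,
    eval_mode: str = "loo",
    ridge: float | None = 1e-6,
) -> ClassificationResult:
    """LDA classification with sensitivity/specificity/ROC-AUC.

    ``eval_mode="loo"`` refits the discriminant with each patient held out
    (the default: resubstitution on ~20 patients is optimistic);
    ``"resubstitution"`` scores the training data.  The ROC/AUC and the
    score-based p-value always use the full-fit discriminant scores (for a
    single biomarker these are a monotone transform of the biomarker
    itself): held-out scores from refitted models are not on a common scale
    and exhibit the well-known leave-one-out score-reversal artifact under
    weak signal, which would bias the AUC below 1/2.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] == 1 and len(labels) > 1:
        X = X.T
    n = len(labels)
    model = fit_lda(X, labels, positive_class, ridge)
    scores = model.decision_function(X)
    coefs = model.coef_
    if eval_mode == "resubstitution":
        predicted = model.predict(X)
    elif eval_mode == "loo":
        predicted = np.empty(n, dtype=labels.dtype)
        for i in range(n):
            keep = np.arange(n) != i
            m = fit_lda(X[keep], labels[keep], positive_class, ridge)
            predicted[i] = m.predict(X[i : i + 1])[0]
    else:
        raise ValueError(f"unknown eval_mode {eval_mode!r}")

    pos = labels == positive_class
    tp = int(np.sum((predicted == positive_class) & pos))
    fn = int(np.sum((predicted != positive_class) & pos))
    tn = int(np.sum((predicted != positive_class) & ~pos))
    fp = int(np.sum((predicted == positive_class) & ~pos))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present in the labels")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    auc = roc_auc(scores, labels, positive_class)[3]
    comp = compare_groups(scores[~pos], scores[pos], biomarker="+".join(biomarkers), visit=visit)
    return ClassificationResult(
        biomarkers=tuple(biomarkers),
        visit=visit,
        eval_mode=eval_mode,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        p_value=comp.p_value,
        scores=scores,
        predicted=predicted,
        coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray  # months
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class SurvivalResult:
    curves: dict  # group -> SurvivalCurve
    statistic: float
    p_value: float


def km_estimate(times, events, group_labels) -> dict:
    """Product-limit (Kaplan-Meier) recurrence-free survival per group.

    At tied times, events are processed before censorings (subjects censored
    at t are still at risk for events at t) — the standard convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group_labels = np.asarray(group_labels)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    curves = {}
    for g in np.unique(group_labels):
        sel = group_labels == g
        kmf = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(times[sel], events[sel])
        t = kmf.survival_function_.index.to_numpy(float)
        s = kmf.survival_function_.iloc[:, 0].to_numpy(float)
        at_risk = np.array([int(np.sum(times[sel] >= ti)) for ti in t])
        curves[str(g)] = SurvivalCurve(group=str(g), times=t, survival=s, at_risk=at_risk)
    return curves


def logrank(times, events, group_labels) -> SurvivalResult:
    """Two-group log-rank test (O-E chi-square, hypergeometric variance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if not events.any():
        raise ValueError("log-rank test undefined with no events")
    a = group_labels == groups[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return SurvivalResult(
        curves=km_estimate(times, events, group_labels),
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )
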