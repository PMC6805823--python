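"""Diagnostic-performance statistics.

2x2 metrics with exact (Clopper-Pearson) 95 % confidence intervals,
likelihood ratios, Bayesian post-test probability, ROC/AUC with the
Hanley-McNeil variance, the DeLong test for paired AUC comparison, the
Hanley z-test for unpaired comparison, Pearson chi-square (no
continuity correction), basic t/ANOVA/correlation tests, and stratified
performance tables.

Conventions that matter for reproducing printed reports: CIs are exact
binomial; the chi-square has no Yates correction; ROC ties get half
credit (Mann-Whitney); likelihood ratios are reported unrounded and
satisfy the Bayes identities post(prev, PLR) = PPV and
1 - post(prev, NLR) = NPV exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for k in ("tp", "fp", "tn", "fn"):
            v = getattr(self, k)
            if v < 0 or v != int(v):
                raise ValueError(f"{k} must be a non-negative integer, got {v}")
            setattr(self, k, int(v))
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion_matrix(predictions, truth) -> ConfusionMatrix:
    """Tally binary predictions against the significant-CAD truth."""
    p = np.asarray(predictions).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return ConfusionMatrix(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


@dataclass
class Proportion:
    """Point estimate with an exact 95 % CI; NaN when undefined."""

    value: float
    ci_low: float
    ci_high: float
    k: int = 0
    n: int = 0

    @property
    def pct(self) -> float:
        return round(100.0 * self.value, 1)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return (round(100.0 * self.ci_low, 1), round(100.0 * self.ci_high, 1))

    def __str__(self) -> str:
        if math.isnan(self.value):
            return "-"
        lo, hi = self.ci_pct
        return f"{self.pct}% ({lo}-{hi}%)"


def exact_proportion(k: int, n: int, alpha: float = 0.05, method: str = "beta") -> Proportion:
    """Binomial proportion with CI; ``method`` follows statsmodels
    (default 'beta' = Clopper-Pearson exact, the method that reproduces
    published exact bounds; 'wilson' available for comparison)."""
    if n == 0:
        return Proportion(float("nan"), float("nan"), float("nan"), 0, 0)
    lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
    return Proportion(k / n, float(lo), float(hi), k, n)


@dataclass
class DiagnosticSummary:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    plr: float
    nlr: float
    prevalence: float
    cm: ConfusionMatrix

    def as_dict(self) -> dict:
        def prop(p):
            return {"pct": p.pct, "ci_pct": list(p.ci_pct), "k": p.k, "n": p.n}
        return {
            "sensitivity": prop(self.sensitivity), "specificity": prop(self.specificity),
            "ppv": prop(self.ppv), "npv": prop(self.npv),
            "plr": None if math.isnan(self.plr) else round(self.plr, 2),
            "nlr": None if math.isnan(self.nlr) else round(self.nlr, 2),
            "prevalence_pct": round(100 * self.prevalence, 1),
            "counts": {"tp": self.cm.tp, "fp": self.cm.fp, "tn": self.cm.tn, "fn": self.cm.fn},
        }


def diagnostic_summary(cm: ConfusionMatrix, ci_method: str = "beta") -> DiagnosticSummary:
    """All 2x2 metrics with exact 95 % CIs.

    Metrics with a zero denominator come back as NaN proportions rather
    than failing the whole summary.
    """
    sens = exact_proportion(cm.tp, cm.positives, method=ci_method)
    spec = exact_proportion(cm.tn, cm.negatives, method=ci_method)
    ppv = exact_proportion(cm.tp, cm.tp + cm.fp, method=ci_method)
    npv = exact_proportion(cm.tn, cm.tn + cm.fn, method=ci_method)
    plr, nlr = likelihood_ratios(sens.value, spec.value)
    prev = cm.positives / cm.total
    return DiagnosticSummary(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                             plr=plr, nlr=nlr, prevalence=prev, cm=cm)


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """(PLR, NLR) = (sens/(1-spec), (1-sens)/spec); infinities/NaN are
    returned (not raised) at the boundaries, flagged by a warning."""
    if math.isnan(sensitivity) or math.isnan(specificity):
        return (float("nan"), float("nan"))
    if specificity >= 1.0:
        warnings.warn("specificity = 1: PLR infinite")
        plr = float("inf") if sensitivity > 0 else float("nan")
    else:
        plr = sensitivity / (1.0 - specificity)
    if specificity <= 0.0:
        warnings.warn("specificity = 0: NLR undefined")
        nlr = float("nan")
    else:
        nlr = (1.0 - sensitivity) / specificity
    return (plr, nlr)


def post_test_probability(prevalence: float, likelihood_ratio: float) -> float:
    """Bayes: post-odds = pre-odds * LR, converted back to probability."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be strictly inside (0, 1): {prevalence}")
    if likelihood_ratio < 0:
        raise ValueError("likelihood ratio must be >= 0")
    odds = prevalence / (1.0 - prevalence) * likelihood_ratio
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U (ties count 0.5)."""
    pos = scores[labels]
    neg = scores[~labels]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    v = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
         + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return math.sqrt(max(v, 0.0))


def roc_auc(scores, labels, alpha: float = 0.05) -> ROCResult:
    """ROC curve and AUC with a Hanley-McNeil Wald CI (clipped to [0,1])."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes required for ROC analysis")
    auc = _auc_mann_whitney(s, y)
    fpr, tpr, _ = roc_curve(y.astype(int), s)
    se = hanley_mcneil_se(auc, int(y.sum()), int((~y).sum()))
    z = sps.norm.ppf(1 - alpha / 2)
    return ROCResult(auc=auc, ci_low=max(auc - z * se, 0.0), ci_high=min(auc + z * se, 1.0),
                     fpr=fpr, tpr=tpr, n_pos=int(y.sum()), n_neg=int((~y).sum()))


@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"invalid p-value {self.p_value}")


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one marker."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # V10[i] = P(pos_i > neg) with ties 0.5, via midranks
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return v10, v01, auc


def delong_paired_test(scores_a, scores_b, labels) -> StatTestResult:
    """DeLong two-sided test for the difference of two correlated AUCs
    measured on the same patients."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired scores and labels must share one length")
    if y.all() or not y.any():
        raise ValueError("both classes required")
    v10a, v01a, auc_a = _delong_components(a, y)
    v10b, v01b, auc_b = _delong_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        warnings.warn("zero variance of AUC difference; p = 1")
        return StatTestResult(statistic=0.0, p_value=1.0, method="delong")
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    return StatTestResult(statistic=float(z), p_value=float(2 * sps.norm.sf(abs(z))),
                          method="delong")


def hanley_unpaired_test(auc_a: float, n_pos_a: int, n_neg_a: int,
                         auc_b: float, n_pos_b: int, n_neg_b: int) -> StatTestResult:
    """z-test for two independent AUCs with Hanley-McNeil variances."""
    for v in (n_pos_a, n_neg_a, n_pos_b, n_neg_b):
        if v < 2:
            raise ValueError("need at least 2 patients per class per group")
    se = math.hypot(hanley_mcneil_se(auc_a, n_pos_a, n_neg_a),
                    hanley_mcneil_se(auc_b, n_pos_b, n_neg_b))
    if se == 0:
        return StatTestResult(statistic=0.0, p_value=1.0, method="hanley")
    z = (auc_a - auc_b) / se
    return StatTestResult(statistic=float(z), p_value=float(2 * sps.norm.sf(abs(z))),
                          method="hanley")


# ---------------------------------------------------------------------------
# generic tests

def chi_square_test(table) -> StatTestResult:
    """Pearson chi-square on a 2x2 (or RxC) table, df = (R-1)(C-1),
    WITHOUT continuity correction."""
    tab = np.asarray(table, dtype=float)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(tab, correction=False)
    return StatTestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          method="chi-square")


def t_test(x, y) -> StatTestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise ValueError("zero variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return StatTestResult(statistic=float(t), p_value=float(p), method="t")


def anova_test(*groups) -> StatTestResult:
    for g in groups:
        if len(g) < 2:
            raise ValueError("need >= 2 observations per group")
    f, p = sps.f_oneway(*[np.asarray(g, float) for g in groups])
    return StatTestResult(statistic=float(f), p_value=float(p), method="anova")


def pearson_test(x, y) -> StatTestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return StatTestResult(statistic=float(r), p_value=float(p), method="pearson")


# ---------------------------------------------------------------------------

def stratified_performance(cohort: pd.DataFrame, stratifier: str,
                           score_col: str = "cad_score", threshold: int = 20,
                           event_level: str = "significant_cad") -> dict[str, dict]:
    """Per-stratum diagnostic summaries + AUC, same machinery as pooled.

    Strata with one class only get their AUC omitted (None); empty
    strata are skipped with a warning.
    """
    out: dict[str, dict] = {}
    for value, sub in cohort.groupby(stratifier, sort=True):
        if len(sub) == 0:
            warnings.warn(f"stratum {value!r} empty; skipped")
            continue
        truth = (sub["disease_level"] == event_level).to_numpy()
        pred = (sub[score_col].to_numpy(float) > threshold)
        cm = confusion_matrix(pred, truth)
        entry: dict = {"n": len(sub), "summary": diagnostic_summary(cm)}
        if truth.any() and not truth.all():
            entry["roc"] = roc_auc(sub[score_col].to_numpy(float), truth)
        else:
            entry["roc"] = None
        out[str(value)] = entry
    return out
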