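"""Risk-stratification evaluation: diagnostics, quartiles, ROC, logistic fits.

Mirrors the standard evaluation surface for a case-control polygenic score:

* median-cutoff diagnostics — subjects are classified positive when their
  score is *strictly greater* than the control median (ties at the cutoff
  count as negative, which makes control specificity >= 0.5 by
  construction);
* quartile stratification with odds ratios against the bottom quartile;
* ROC/AUC via the Mann-Whitney identity with Hanley-McNeil (default) or
  DeLong confidence intervals;
* case-only subgroup analyses (is a clinical subgroup enriched above the
  population-control median?);
* Pearson chi-square tests of independence and maximum-likelihood logistic
  regression with Wald intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import ValidationError

__all__ = [
    "DiagnosticSummary",
    "RocCurve",
    "QuartileTable",
    "LogisticFit",
    "SubgroupSummary",
    "odds_ratio_2x2",
    "median_cutoff_summary",
    "quartile_stratification",
    "roc_auc",
    "subgroup_summary",
    "chi_square_independence",
    "cochran_armitage_trend",
    "logistic_fit",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class DiagnosticSummary:
    """2x2 diagnostic metrics of a score cutoff."""

    cutoff: float
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_positive: float
    odds_ratio: float
    or_ci: tuple[float, float]
    or_pvalue: float

    @classmethod
    def from_counts(
        cls, cutoff: float, tp: int, fn: int, fp: int, tn: int
    ) -> "DiagnosticSummary":
        if min(tp, fn, fp, tn) < 0:
            raise ValidationError("counts must be non-negative")
        if tp + fn == 0 or fp + tn == 0:
            raise ValidationError("need at least one case and one control")
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ppv = tp / (tp + fp) if tp + fp else math.nan
        npv = tn / (tn + fn) if tn + fn else math.nan
        lrp = sens / (1.0 - spec) if spec < 1.0 else math.inf
        or_, ci, p = odds_ratio_2x2(tp, fn, fp, tn)
        return cls(cutoff, tp, fn, fp, tn, sens, spec, ppv, npv, lrp, or_, ci, p)


def odds_ratio_2x2(
    a: int, b: int, c: int, d: int
) -> tuple[float, tuple[float, float], float]:
    """Cross-product odds ratio ``ad/bc`` with Woolf 95% CI and Wald p.

    Layout: ``a``/``b`` = exposed/unexposed among cases, ``c``/``d`` among
    controls (any layout with the same cross product is equivalent).  A
    zero cell triggers the Haldane-Anscombe +0.5 correction on all cells,
    with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("odds_ratio_2x2: counts must be non-negative")
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if min(aa, bb, cc, dd) == 0.0:
        warnings.warn(
            "odds_ratio_2x2: zero cell, applying Haldane-Anscombe +0.5",
            stacklevel=2,
        )
        aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
    log_or = math.log(aa * dd / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (math.exp(log_or - _Z975 * se), math.exp(log_or + _Z975 * se))
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return math.exp(log_or), ci, float(p)


def median_cutoff_summary(
    case_scores, control_scores
) -> DiagnosticSummary:
    """Diagnostics of the above-control-median classifier.

    Cutoff = median of the control scores; positive = strictly greater.
    For tie-free continuous controls with an even count the specificity is
    exactly 0.5 (the median falls between the two middle order statistics).
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("median_cutoff_summary: empty group")
    cutoff = float(np.median(controls))
    tp = int(np.sum(cases > cutoff))
    fp = int(np.sum(controls > cutoff))
    return DiagnosticSummary.from_counts(
        cutoff, tp, cases.size - tp, fp, controls.size - fp
    )


@dataclass(frozen=True)
class QuartileTable:
    """Case/control distribution over score quartiles, ORs vs Q1."""

    boundaries: tuple[float, float, float]
    case_counts: tuple[int, int, int, int]
    control_counts: tuple[int, int, int, int]
    case_pct: tuple[float, float, float, float]
    control_pct: tuple[float, float, float, float]
    or_vs_q1: tuple[float, float, float]
    or_ci_vs_q1: tuple[tuple[float, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quartile": ["Q1", "Q2", "Q3", "Q4"],
                "cases": self.case_counts,
                "case_pct": self.case_pct,
                "controls": self.control_counts,
                "control_pct": self.control_pct,
                "or_vs_q1": (1.0,) + self.or_vs_q1,
                "or_ci_low": (math.nan,) + tuple(c[0] for c in self.or_ci_vs_q1),
                "or_ci_high": (math.nan,) + tuple(c[1] for c in self.or_ci_vs_q1),
            }
        )


def _quartile_bins(scores: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    # bin k = number of boundaries strictly below the score; ties at a
    # boundary fall into the lower quartile, consistent with the
    # strictly-greater cutoff rule
    return (scores[:, None] > boundaries[None, :]).sum(axis=1)


def quartile_stratification(
    case_scores, control_scores, basis: str = "pooled"
) -> QuartileTable:
    """Quartile table with per-quartile odds ratios against Q1.

    Boundaries are linear-interpolation empirical quartiles of the pooled
    study population by default (``basis="controls"`` uses the controls
    only).  Each OR vs Q1 comes from the 2x2 cross product with Woolf CI.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size + controls.size < 8:
        raise ValidationError("quartile_stratification: need >= 8 subjects")
    if basis == "pooled":
        ref = np.concatenate([cases, controls])
    elif basis == "controls":
        ref = controls
    else:
        raise ValidationError(f"unknown quartile basis {basis!r}")
    bounds = np.quantile(ref, [0.25, 0.5, 0.75])  # "type 7" interpolation
    cq = np.bincount(_quartile_bins(cases, bounds), minlength=4)
    nq = np.bincount(_quartile_bins(controls, bounds), minlength=4)
    ors, cis = [], []
    for k in (1, 2, 3):
        o, ci, _ = odds_ratio_2x2(int(cq[k]), int(cq[0]), int(nq[k]), int(nq[0]))
        ors.append(o)
        cis.append(ci)
    return QuartileTable(
        tuple(float(b) for b in bounds),
        tuple(int(x) for x in cq),
        tuple(int(x) for x in nq),
        tuple(float(x) for x in 100.0 * cq / cases.size),
        tuple(float(x) for x in 100.0 * nq / controls.size),
        tuple(ors),
        tuple(cis),
    )


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    pvalue_vs_half: float


def _hanley_mcneil_se(auc: float, n_cases: int, n_controls: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_cases - 1) * (q1 - auc**2)
        + (n_controls - 1) * (q2 - auc**2)
    ) / (n_cases * n_controls)
    return math.sqrt(max(var, 0.0))


def _delong_se(cases: np.ndarray, controls: np.ndarray, auc: float) -> float:
    # placement values: V10_i = P(control < case_i) + .5 P(=), and vice versa
    order = np.sort(controls)
    v10 = (
        np.searchsorted(order, cases, side="left")
        + np.searchsorted(order, cases, side="right")
    ) / (2.0 * controls.size)
    order = np.sort(cases)
    v01 = 1.0 - (
        np.searchsorted(order, controls, side="left")
        + np.searchsorted(order, controls, side="right")
    ) / (2.0 * cases.size)
    s10 = v10.var(ddof=1) if cases.size > 1 else 0.0
    s01 = v01.var(ddof=1) if controls.size > 1 else 0.0
    return math.sqrt(s10 / cases.size + s01 / controls.size)


def roc_auc(case_scores, control_scores, ci_method: str = "hanley") -> RocCurve:
    """ROC curve and AUC by the Mann-Whitney identity (ties count 1/2).

    The AUC equals the trapezoidal area under the (fpr, tpr) sweep exactly.
    The p-value tests AUC = 0.5 through the normal approximation of the
    Mann-Whitney U statistic (tie-corrected).  CI: Hanley-McNeil (default)
    or DeLong (``ci_method="delong"``), clipped to [0, 1].
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("roc_auc: empty group")
    if ci_method not in ("hanley", "delong"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    s = np.concatenate([cases, controls])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    degenerate = np.ptp(s) == 0.0
    if degenerate:
        warnings.warn("roc_auc: all scores identical, AUC degenerate at 0.5",
                      stacklevel=2)
        pvalue = 1.0
    else:
        pvalue = float(
            stats.mannwhitneyu(cases, controls, alternative="two-sided",
                               method="asymptotic").pvalue
        )
    if ci_method == "delong" and not degenerate:
        se = _delong_se(cases, controls, auc)
    else:
        se = _hanley_mcneil_se(auc, cases.size, controls.size)
    ci = (max(0.0, auc - _Z975 * se), min(1.0, auc + _Z975 * se))
    return RocCurve(thr, tpr, fpr, auc, ci, pvalue)


@dataclass(frozen=True)
class SubgroupSummary:
    """Case-only analysis: does the PRS separate a clinical subgroup?"""

    n_subgroup: int
    n_other: int
    n_above: int
    frac_above: float
    odds_ratio: float
    or_ci: tuple[float, float]
    or_pvalue: float
    auc: float
    auc_ci: tuple[float, float]
    flagged: bool = False
    reason: str | None = None


def subgroup_summary(
    case_scores, subgroup_flag, control_median_cutoff: float
) -> SubgroupSummary:
    """Above-median enrichment and AUC of the PRS for a case subgroup.

    All inputs are cases; the outcome is subgroup membership.  The odds
    ratio compares above-cutoff odds inside vs outside the subgroup.  A
    subgroup equal to all (or none) of the cases is flagged rather than
    silently producing an undefined OR.
    """
    scores = np.asarray(case_scores, dtype=float)
    flag = np.asarray(subgroup_flag, dtype=bool)
    if scores.shape != flag.shape:
        raise ValidationError("subgroup_summary: misaligned inputs")
    if scores.size == 0 or not flag.any():
        raise ValidationError("subgroup_summary: empty subgroup")
    n_in = int(flag.sum())
    above = scores > control_median_cutoff
    n_above = int(np.sum(above & flag))
    frac = n_above / n_in
    if flag.all():
        return SubgroupSummary(
            n_in, 0, n_above, frac, math.nan, (math.nan, math.nan), math.nan,
            math.nan, (math.nan, math.nan),
            flagged=True, reason="subgroup equals all cases",
        )
    a = n_above
    b = n_in - n_above
    c = int(np.sum(above & ~flag))
    d = int(np.sum(~above & ~flag))
    or_, ci, p = odds_ratio_2x2(a, b, c, d)
    roc = roc_auc(scores[flag], scores[~flag])
    return SubgroupSummary(
        n_in, scores.size - n_in, n_above, frac, or_, ci, p, roc.auc, roc.ci95
    )


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, df = (r-1)(c-1), no correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValidationError("chi_square_independence: need a non-negative 2-D table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("chi_square_independence: zero margin")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cochran_armitage_trend(table, scores=None) -> tuple[float, float]:
    """Cochran-Armitage test for trend in a 2 x k table.

    Rows are (cases, controls) counts over k ordered categories; ``scores``
    default to 0..k-1.  Returns the 1-df chi-square statistic and two-sided
    p-value.  Offered alongside the Pearson test because an ordered
    exposure (score quartiles) often calls for a trend alternative.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or np.any(t < 0):
        raise ValidationError("cochran_armitage_trend: need a 2 x k count table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("cochran_armitage_trend: zero margin")
    k = t.shape[1]
    w = np.arange(k, dtype=float) if scores is None else np.asarray(scores, float)
    if w.shape != (k,):
        raise ValidationError("cochran_armitage_trend: scores length mismatch")
    n_col = t.sum(axis=0)
    n = n_col.sum()
    cases = t[0]
    p = cases.sum() / n
    num = float(np.sum(w * (cases - n_col * p)))
    var = p * (1 - p) * float(np.sum(w**2 * n_col) - np.sum(w * n_col) ** 2 / n)
    if var == 0.0:
        return 0.0, 1.0
    stat = num**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    model_auc: float
    model_auc_ci: tuple[float, float]
    converged: bool
    flagged: bool = False
    reason: str | None = None

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {
            "coef": float(self.coefficients[i]),
            "or": float(self.odds_ratios[i]),
            "ci": (float(self.ci_low[i]), float(self.ci_high[i])),
            "p": float(self.pvalues[i]),
        }


def logistic_fit(outcome, covariates: dict) -> LogisticFit:
    """Fit ``logit P(outcome) = const + X b`` by Newton maximum likelihood.

    ``covariates`` maps term names to aligned numeric vectors.  Reports
    exp(coefficients) with Wald 95% intervals and the in-sample AUC of the
    fitted probabilities.  Non-convergence or separation-scale estimates
    are flagged, never returned silently.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("logistic_fit: outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("logistic_fit: outcome has a single class")
    names = list(covariates)
    if names:
        X = np.column_stack([np.asarray(covariates[k], dtype=float) for k in names])
        if X.shape[0] != y.size:
            raise ValidationError("logistic_fit: covariate length mismatch")
        if not np.all(np.isfinite(X)):
            raise ValidationError("logistic_fit: covariates must be finite")
        Xc = sm.add_constant(X, has_constant="add")
    else:
        Xc = np.ones((y.size, 1))
    terms = tuple(["const"] + names)

    flagged, reason, converged = False, None, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, method="newton",
                                      tol=1e-10)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # singular Hessian / perfect separation
            res = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1e-8, maxiter=200)
            converged = False
    params = np.asarray(res.params, dtype=float)
    try:
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    if not converged or np.any(np.abs(params[1:]) > 15) or not np.all(
        np.isfinite(bse)
    ):
        flagged = True
        reason = "non-convergence or quasi-separation"

    lo = np.exp(params - _Z975 * bse)
    hi = np.exp(params + _Z975 * bse)
    eta = Xc @ params
    if y.min() < y.max() and np.ptp(eta) > 0:
        roc = roc_auc(eta[y == 1], eta[y == 0])
        auc, auc_ci = roc.auc, roc.ci95
    else:
        auc, auc_ci = 0.5, (math.nan, math.nan)
    return LogisticFit(
        terms, params, np.exp(params), lo, hi, pvals, auc, auc_ci,
        converged, flagged, reason,
    )
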