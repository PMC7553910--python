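"""Diagnostics, quartiles, ROC/AUC, chi-square and logistic regression."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from finnprs import (
    ValidationError,
    chi_square_independence,
    cochran_armitage_trend,
    logistic_fit,
    median_cutoff_summary,
    odds_ratio_2x2,
    quartile_stratification,
    roc_auc,
    subgroup_summary,
)


def auc_brute_force(cases, controls):
    """All-pairs Mann-Whitney count; ties contribute 1/2."""
    cases = np.asarray(cases, float)[:, None]
    controls = np.asarray(controls, float)[None, :]
    return float(
        ((cases > controls).sum() + 0.5 * (cases == controls).sum())
        / (cases.size * controls.size)
    )


# --------------------------------------------------------------- median cutoff

def test_median_cutoff_hand_example():
    d = median_cutoff_summary([5, 1, 3], [0, 2, 4])
    assert d.cutoff == 2.0
    assert d.sensitivity == pytest.approx(2 / 3)
    assert d.specificity == pytest.approx(2 / 3)


def test_median_cutoff_exchangeable_groups(rng):
    scores = rng.normal(size=4000)
    d = median_cutoff_summary(scores[:2000], scores[2000:])
    # cutoff noise adds to the binomial noise: tolerance ~3 combined SE
    assert d.sensitivity == pytest.approx(0.5, abs=0.05)
    assert d.specificity == pytest.approx(0.5, abs=0.001)


def test_specificity_exactly_half_for_even_tie_free_controls(rng):
    # strictly-greater rule: the median of an even count of distinct values
    # sits between the two middle order statistics
    controls = rng.normal(size=500) * 10  # 500 distinct continuous values
    d = median_cutoff_summary(rng.normal(size=100), controls)
    assert d.specificity == 0.5


def test_median_cutoff_cross_product_from_printed_counts():
    from finnprs.evaluate import DiagnosticSummary

    d = DiagnosticSummary.from_counts(0.0, 1868, 870, 1200, 1200)
    assert d.odds_ratio == pytest.approx(1868 * 1200 / (870 * 1200), rel=1e-12)
    assert d.odds_ratio == pytest.approx(2.1471, abs=5e-5)


def test_median_cutoff_empty_group_rejected():
    with pytest.raises(ValidationError):
        median_cutoff_summary([], [1, 2])


# ------------------------------------------------------------------ odds ratio

def test_odds_ratio_examples():
    or_, ci, p = odds_ratio_2x2(10, 5, 4, 8)
    assert or_ == pytest.approx(4.0, rel=1e-12)
    assert ci[0] < 4.0 < ci[1]
    or_, _, p = odds_ratio_2x2(5, 5, 5, 5)
    assert or_ == pytest.approx(1.0) and p == pytest.approx(1.0)


def test_odds_ratio_zero_cell_correction():
    with pytest.warns(UserWarning, match="Haldane"):
        or_, ci, _ = odds_ratio_2x2(10, 0, 5, 5)
    assert math.isfinite(or_) and math.isfinite(ci[1])


@given(st.tuples(*[st.integers(1, 500)] * 4))
def test_diagnostic_identities(counts):
    from finnprs.evaluate import DiagnosticSummary

    tp, fn, fp, tn = counts
    d = DiagnosticSummary.from_counts(0.0, tp, fn, fp, tn)
    assert d.sensitivity == pytest.approx(tp / (tp + fn), rel=1e-15)
    assert d.specificity == pytest.approx(tn / (tn + fp), rel=1e-15)
    assert d.ppv == pytest.approx(tp / (tp + fp), rel=1e-15)
    assert d.npv == pytest.approx(tn / (tn + fn), rel=1e-15)
    assert d.lr_positive == pytest.approx(
        d.sensitivity / (1 - d.specificity), rel=1e-12)
    assert 0 <= d.sensitivity <= 1 and 0 <= d.specificity <= 1


# -------------------------------------------------------------------- quartiles

def test_quartile_hand_enumeration():
    # pooled 1..8; cases hold the top four scores
    q = quartile_stratification([5, 6, 7, 8], [1, 2, 3, 4])
    assert q.case_pct == (0.0, 0.0, 50.0, 50.0)
    assert q.control_pct == (50.0, 50.0, 0.0, 0.0)


def test_quartile_null_ors_cover_one(rng):
    scores = rng.normal(size=20_000)
    q = quartile_stratification(scores[:10_000], scores[10_000:])
    for or_, (lo, hi) in zip(q.or_vs_q1, q.or_ci_vs_q1):
        assert lo < 1.0 < hi


def test_quartile_counts_reconcile(rng):
    cases, controls = rng.normal(1, 1, 503), rng.normal(0, 1, 401)
    q = quartile_stratification(cases, controls)
    assert sum(q.case_counts) == 503 and sum(q.control_counts) == 401
    assert sum(q.case_pct) == pytest.approx(100.0, abs=0.1)
    assert sum(q.control_pct) == pytest.approx(100.0, abs=0.1)


def test_quartile_basis_modes_differ(rng):
    cases, controls = rng.normal(2, 1, 400), rng.normal(0, 1, 400)
    pooled = quartile_stratification(cases, controls, basis="pooled")
    ctrl = quartile_stratification(cases, controls, basis="controls")
    assert pooled.boundaries != ctrl.boundaries
    with pytest.raises(ValidationError):
        quartile_stratification(cases, controls, basis="cases")
    with pytest.raises(ValidationError):
        quartile_stratification([1, 2], [3, 4])


# -------------------------------------------------------------------------- ROC

def test_roc_hand_example_with_tie():
    r = roc_auc([2, 3], [1, 2])
    assert r.auc == pytest.approx(0.875, rel=1e-12)


def test_roc_perfect_separation():
    r = roc_auc([10, 11, 12], [1, 2, 3])
    assert r.auc == 1.0


def test_roc_complement_symmetry(rng):
    for _ in range(10):
        a = rng.normal(size=rng.integers(2, 40))
        b = rng.choice(np.r_[a, rng.normal(size=30)], size=rng.integers(2, 40))
        assert roc_auc(a, b).auc + roc_auc(b, a).auc == pytest.approx(1.0, rel=1e-12)


def test_roc_matches_brute_force_pairwise(rng):
    """Mann-Whitney/trapezoid AUC equals explicit all-pairs counting."""
    for _ in range(25):
        n1, n0 = rng.integers(1, 200), rng.integers(1, 200)
        # integer scores force plenty of ties
        cases = rng.integers(0, 12, n1).astype(float)
        controls = rng.integers(0, 12, n0).astype(float)
        r = roc_auc(cases, controls)
        assert r.auc == pytest.approx(auc_brute_force(cases, controls),
                                      rel=1e-12, abs=1e-12)
        # the curve itself is a valid monotone sweep
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)


def test_roc_degenerate_constant_scores():
    with pytest.warns(UserWarning, match="degenerate"):
        r = roc_auc([1.0, 1.0], [1.0, 1.0])
    assert r.auc == 0.5


def test_roc_delong_ci_close_to_hanley(rng):
    cases, controls = rng.normal(0.5, 1, 300), rng.normal(0, 1, 300)
    h = roc_auc(cases, controls, ci_method="hanley")
    d = roc_auc(cases, controls, ci_method="delong")
    assert h.auc == d.auc
    assert h.ci95[0] == pytest.approx(d.ci95[0], abs=0.02)


# ------------------------------------------------------------------- subgroups

def test_subgroup_degenerate_all_cases_flagged(rng):
    s = rng.normal(size=50)
    res = subgroup_summary(s, np.ones(50, bool), 0.0)
    assert res.flagged
    with pytest.raises(ValidationError):
        subgroup_summary(s, np.zeros(50, bool), 0.0)


def test_subgroup_null_independence(rng):
    scores = rng.normal(size=20_000)
    flag = rng.random(20_000) < 0.3
    res = subgroup_summary(scores, flag, 0.0)
    assert res.auc == pytest.approx(0.5, abs=0.015)
    assert res.or_ci[0] < 1.0 < res.or_ci[1]


# ------------------------------------------------------------------ chi-square

def test_chi_square_hand_computation():
    stat, df, _ = chi_square_independence([[10, 10], [5, 15]])
    assert stat == pytest.approx(2.6667, abs=5e-5)
    assert df == 1


def test_cochran_armitage_matches_subject_level_correlation(rng):
    """CA trend chi-square equals N*r^2 with r the subject-level Pearson
    correlation between category score and case indicator."""
    for _ in range(10):
        table = rng.integers(1, 60, size=(2, 4))
        w = np.arange(4.0)
        y, x = [], []
        for j in range(4):
            y += [1] * table[0, j] + [0] * table[1, j]
            x += [w[j]] * (table[0, j] + table[1, j])
        y, x = np.asarray(y, float), np.asarray(x, float)
        n = y.size
        r = np.corrcoef(x, y)[0, 1]
        stat, p = cochran_armitage_trend(table)
        assert stat == pytest.approx(n * r**2, rel=1e-10)
        assert 0.0 <= p <= 1.0
    # proportional rows carry no trend
    stat, p = cochran_armitage_trend(np.outer([1, 2], [5, 10, 15, 20]))
    assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        cochran_armitage_trend([[1, 2, 3], [4, 5, 6], [7, 8, 9]])


def test_chi_square_degenerate_tables():
    stat, _, p = chi_square_independence([[10, 20], [20, 40]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    # 4x2 proportional rows
    t = np.outer([1, 2, 3, 4], [10, 30])
    stat, df, _ = chi_square_independence(t)
    assert stat == pytest.approx(0.0, abs=1e-9) and df == 3
    with pytest.raises(ValidationError):
        chi_square_independence([[0, 0], [1, 2]])


# -------------------------------------------------------------------- logistic

def test_logistic_single_binary_covariate_equals_cross_product():
    # 2x2 (10, 5, 4, 8): saturated fit, slope = ln 4 exactly
    x = np.r_[np.ones(10), np.zeros(5), np.ones(4), np.zeros(8)]
    y = np.r_[np.ones(15), np.zeros(12)]
    fit = logistic_fit(y, {"x": x})
    assert fit.term("x")["or"] == pytest.approx(4.0, rel=1e-8)
    assert fit.term("x")["coef"] == pytest.approx(math.log(4.0), rel=1e-8)


@given(st.tuples(*[st.integers(2, 60)] * 4))
def test_logistic_reproduces_woolf_or_on_random_tables(counts):
    a, b, c, d = counts
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    fit = logistic_fit(y, {"x": x})
    or_ref, ci_ref, _ = odds_ratio_2x2(a, b, c, d)
    assert fit.term("x")["or"] == pytest.approx(or_ref, rel=1e-6)
    lo, hi = fit.term("x")["ci"]
    assert lo == pytest.approx(ci_ref[0], rel=1e-5)
    assert hi == pytest.approx(ci_ref[1], rel=1e-5)


def test_logistic_intercept_only_recovers_case_fraction():
    y = np.r_[np.ones(30), np.zeros(70)]
    fit = logistic_fit(y, {})
    p_hat = 1 / (1 + math.exp(-fit.coefficients[0]))
    assert p_hat == pytest.approx(0.3, rel=1e-8)


def test_logistic_null_covariate_ci_covers_one(rng):
    y = rng.integers(0, 2, 2000).astype(float)
    x = rng.normal(size=2000)
    fit = logistic_fit(y, {"x": x})
    lo, hi = fit.term("x")["ci"]
    assert lo < 1.0 < hi and not fit.flagged


def test_logistic_separation_is_flagged():
    y = np.r_[np.ones(20), np.zeros(20)]
    x = np.r_[np.ones(20), np.zeros(20)] * 5.0
    fit = logistic_fit(y, {"x": x})
    assert fit.flagged


def test_logistic_input_validation():
    with pytest.raises(ValidationError):
        logistic_fit([1, 1, 1], {"x": [1, 2, 3]})
    with pytest.raises(ValidationError):
        logistic_fit([0, 1, 2], {"x": [1, 2, 3]})
    with pytest.raises(ValidationError):
        logistic_fit([0, 1], {"x": [1.0, math.inf]})
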