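"""Panel records, BH FDR, the selection funnel, HWE and per-SNP ORs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from finnprs import (
    EmptyPanelError,
    SelectionCriteria,
    SnpPanel,
    ValidationError,
    allelic_or,
    bh_fdr,
    hwe_check,
    read_panel_tsv,
    select_snps,
    write_panel_tsv,
)
from finnprs.panel import partition_candidates

from .conftest import make_snp


# --------------------------------------------------------------------- BH FDR

def bh_stepup_brute(pvalues):
    """Literal step-up definition: q_(k) = min_{l >= k} p_(l) * m / (l+1)."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.mark.parametrize(
    "pvalues, expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0], [1.0]),
        ([0.05, 0.001], [0.05, 0.002]),
    ],
)
def test_bh_fdr_known_values(pvalues, expected):
    np.testing.assert_allclose(bh_fdr(pvalues), expected, rtol=1e-12)


@given(
    st.lists(
        st.sampled_from([0.01, 0.02, 0.03, 0.04, 0.05, 1.0]),
        min_size=1,
        max_size=6,
    )
)
def test_bh_fdr_matches_stepup_definition(pvalues):
    np.testing.assert_allclose(bh_fdr(pvalues), bh_stepup_brute(pvalues),
                               rtol=1e-12)


@given(
    st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=2, max_size=12),
    st.randoms(use_true_random=False),
)
def test_bh_fdr_permutation_equivariant(pvalues, rnd):
    perm = list(range(len(pvalues)))
    rnd.shuffle(perm)
    q = bh_fdr(pvalues)
    q_perm = bh_fdr([pvalues[i] for i in perm])
    np.testing.assert_allclose(q_perm, q[perm], rtol=1e-12)
    assert np.all(q >= np.asarray(pvalues) - 1e-15)
    assert np.all((q > 0) & (q <= 1))


@pytest.mark.parametrize("bad", [[], [0.0, 0.5], [0.5, 1.2], [np.nan]])
def test_bh_fdr_rejects_invalid(bad):
    with pytest.raises(ValidationError):
        bh_fdr(bad)


# ------------------------------------------------------------------ selection

def test_select_snps_applies_significance_and_effect_bounds():
    near_null = make_snp("rs_a", or_=1.05, pvalue=1e-9)
    not_gw = make_snp("rs_b", or_=1.3, pvalue=1e-7)
    protective = make_snp("rs_c", or_=0.85, pvalue=1e-9)
    risk = make_snp("rs_d", or_=1.3, pvalue=1e-9)
    panel = select_snps([near_null, not_gw, protective, risk])
    assert panel.rsids == ["rs_c", "rs_d"]


def test_select_snps_empty_survivors_is_an_error():
    with pytest.raises(EmptyPanelError):
        select_snps([make_snp(or_=1.05)])


def test_partition_is_exhaustive_and_disjoint():
    cands = [
        make_snp(f"rs{i}", or_=o, pvalue=p)
        for i, (o, p) in enumerate(
            [(1.2, 1e-9), (1.05, 1e-10), (0.85, 1e-3), (1.5, 1e-20), (0.95, 1e-9)]
        )
    ]
    kept, rejected = partition_candidates(cands, SelectionCriteria())
    assert sorted(r.rsid for r in kept + rejected) == sorted(r.rsid for r in cands)
    assert not {r.rsid for r in kept} & {r.rsid for r in rejected}


def test_fdr_stage_filters_before_thresholds():
    # rs_hi would pass p/OR bounds but its BH q across the candidate list
    # exceeds the threshold supplied
    strong = [make_snp(f"rs{i}", or_=1.3, pvalue=1e-12) for i in range(3)]
    weak = make_snp("rs_hi", or_=1.3, pvalue=4.9e-8)
    panel = select_snps(strong + [weak], SelectionCriteria(fdr_threshold=1e-9))
    assert "rs_hi" not in panel.rsids
    # with FDR off the same record survives
    panel = select_snps(strong + [weak], SelectionCriteria(fdr_threshold=None))
    assert "rs_hi" in panel.rsids


def test_panel_invariants():
    with pytest.raises(ValidationError):
        SnpPanel.from_records([make_snp("rs1"), make_snp("rs1")])
    with pytest.raises(ValidationError):
        make_snp(eaf=1.0)
    with pytest.raises(ValidationError):
        make_snp(ea="A", oa="A")
    p = SnpPanel.from_records([make_snp("rs9", or_=1.25)])
    assert p.weights[0] == pytest.approx(math.log(1.25), abs=0)


# ------------------------------------------------------------------------ HWE

def test_hwe_exact_proportions_give_zero():
    res = hwe_check((25, 50, 25))
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.passed


def test_hwe_extreme_departure():
    res = hwe_check((50, 0, 50))
    assert res.chi_square == pytest.approx(100.0)
    assert not res.passed


def test_hwe_monomorphic_passes_with_warning():
    with pytest.warns(UserWarning, match="monomorphic"):
        res = hwe_check((0, 0, 10))
    assert res.chi_square == 0.0 and res.passed and res.monomorphic


def test_hwe_zero_total_rejected():
    with pytest.raises(ValidationError):
        hwe_check((0, 0, 0))


def test_hwe_zero_iff_observed_equals_expected():
    # (18, 24, 8): p = 0.4, expected (18, 24, 8) exactly
    assert hwe_check((18, 24, 8)).chi_square == pytest.approx(0.0, abs=1e-12)
    assert hwe_check((19, 22, 9)).chi_square > 0.0


# ------------------------------------------------------------------ allelic OR

def test_allelic_or_binary_predictor_equals_cross_product():
    # carriers (dosage 1) vs non-carriers: a=30 case-carriers, b=20 cases,
    # c=15 control-carriers, d=35 controls -> OR = 30*35/(20*15) = 3.5
    d = np.array([1] * 30 + [0] * 20 + [1] * 15 + [0] * 35)
    y = np.array([1] * 50 + [0] * 50)
    res = allelic_or(d, y)
    assert res.odds_ratio == pytest.approx(3.5, rel=1e-6)
    assert not res.flagged


def test_allelic_or_independent_balanced_table_is_one():
    d = np.tile([0, 1, 2], 20)
    y = np.repeat([0, 1], 30)
    res = allelic_or(d, y)
    assert res.odds_ratio == pytest.approx(1.0, rel=1e-8)
    assert res.ci_low < 1.0 < res.ci_high


def test_allelic_or_constant_dosage_flagged():
    res = allelic_or([1, 1, 1, 1], [0, 1, 0, 1])
    assert res.flagged and res.reason == "no dosage variation"


def test_allelic_or_perfect_separation_flagged():
    d = np.array([2] * 20 + [0] * 20)
    y = np.array([1] * 20 + [0] * 20)
    res = allelic_or(d, y)
    assert res.flagged and res.ci_high == math.inf


def test_allelic_or_input_validation():
    with pytest.raises(ValidationError):
        allelic_or([0, 1, 3], [0, 1, 1])
    with pytest.raises(ValidationError):
        allelic_or([0, 1, 2], [1, 1, 1])


# ---------------------------------------------------------------- TSV round trip

def test_panel_tsv_round_trip_lossless(tmp_path, rng):
    records = [
        make_snp(
            f"rs{i}",
            eaf=float(rng.uniform(0.01, 0.99)),
            or_=float(rng.uniform(0.5, 2.0)),
            pvalue=float(10 ** rng.uniform(-30, -1)),
            pos=int(rng.integers(1, 2**31)),
            chrom=str(rng.integers(1, 23)),
        )
        for i in range(30)
    ]
    panel = SnpPanel.from_records(records)
    path = tmp_path / "panel.tsv"
    write_panel_tsv(panel, path)
    back = read_panel_tsv(path)
    assert back.rsids == panel.rsids
    for a, b in zip(panel.records, back.records):
        assert b.effect_allele_freq == pytest.approx(a.effect_allele_freq, rel=1e-14)
        assert b.per_allele_or == pytest.approx(a.per_allele_or, rel=1e-14)
        assert b.pvalue == pytest.approx(a.pvalue, rel=1e-14)
        assert (b.chrom, b.pos, b.effect_allele, b.other_allele) == (
            a.chrom, a.pos, a.effect_allele, a.other_allele)
    assert back.sha256() == panel.sha256()


def test_default_panel_is_a_valid_selection(panel55):
    assert len(panel55) == 55
    ors = np.exp(panel55.weights)
    assert np.all((ors > 1.1) | (ors < 0.9))
    # every locus passes the funnel it is meant to have survived
    assert len(select_snps(panel55.records)) == 55
    n_protective = int(np.sum(ors < 1.0))
    assert n_protective == 8
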