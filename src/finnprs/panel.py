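"""SNP weight panels: records, the selection funnel, and per-SNP QC statistics.

A weight panel lists the susceptibility loci that enter a polygenic risk
score.  Each locus carries an effect allele, that allele's population
frequency ``p_i``, and a per-allele odds ratio ``OR_i`` estimated from a
case-control association scan; the score weight is ``beta_i = ln(OR_i)``.

Selection follows the conventional funnel for a population-specific panel:
multiple-testing correction (Benjamini-Hochberg FDR, optional because
pre-computed q-values may be supplied), genome-wide significance
(``p < 5e-8``), and an effect-size bound that keeps risk loci (OR > 1.1)
and protective loci (OR < 0.9) while discarding near-null hits.

Per-SNP QC provided here: a 1-df asymptotic Hardy-Weinberg equilibrium
chi-square test on genotype counts, and per-allele odds ratios from a
maximum-likelihood logistic regression of case status on dosage.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyPanelError, FormatError, ValidationError

__all__ = [
    "SnpRecord",
    "SnpPanel",
    "SelectionCriteria",
    "HweResult",
    "AllelicOrResult",
    "bh_fdr",
    "select_snps",
    "partition_candidates",
    "hwe_check",
    "allelic_or",
    "read_panel_tsv",
    "write_panel_tsv",
    "load_default_panel",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """One locus of a weight panel.

    Parameters
    ----------
    rsid : str
        dbSNP-style identifier; unique within a panel.
    chrom : str
        Chromosome label (stored as text; "1".."22", "X", ...).
    pos : int
        1-based position, informational only (loci are keyed by rsid).
    effect_allele : str
        The allele whose dosage (0, 1 or 2 copies) enters the score.
    other_allele : str
        The non-effect allele.
    effect_allele_freq : float
        Population frequency of the effect allele, strictly inside (0, 1).
    per_allele_or : float
        Per-allele odds ratio for disease; > 1 risk, < 1 protective.
    pvalue : float
        Association p-value in (0, 1].
    fdr_q : float or None
        Pre-computed Benjamini-Hochberg q-value, if available.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    effect_allele_freq: float
    per_allele_or: float
    pvalue: float
    fdr_q: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be a non-empty string")
        if not (0.0 < self.effect_allele_freq < 1.0):
            raise ValidationError(
                f"{self.rsid}: effect_allele_freq must be in (0,1), "
                f"got {self.effect_allele_freq}"
            )
        if not self.per_allele_or > 0.0:
            raise ValidationError(f"{self.rsid}: per_allele_or must be > 0")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.rsid}: pvalue must be in (0,1]")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are equal")
        for a in (self.effect_allele, self.other_allele):
            if not set(a) <= _BASES or not a:
                raise ValidationError(f"{self.rsid}: allele {a!r} is not A/C/G/T")
        if self.fdr_q is not None and not (0.0 < self.fdr_q <= 1.0):
            raise ValidationError(f"{self.rsid}: fdr_q must be in (0,1]")
        if int(self.pos) < 1:
            raise ValidationError(f"{self.rsid}: pos must be >= 1")

    @property
    def beta(self) -> float:
        """Score weight, ln(per-allele OR)."""
        return math.log(self.per_allele_or)


@dataclass(frozen=True)
class SnpPanel:
    """An ordered collection of :class:`SnpRecord` with unique rsids."""

    records: tuple[SnpRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyPanelError("panel has no records")
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            dup = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsids in panel: {dup}")

    @classmethod
    def from_records(cls, records: Iterable[SnpRecord]) -> "SnpPanel":
        return cls(tuple(records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    @property
    def weights(self) -> np.ndarray:
        """beta_i = ln(OR_i), aligned with ``records``."""
        return np.array([r.beta for r in self.records])

    @property
    def effect_allele_freqs(self) -> np.ndarray:
        return np.array([r.effect_allele_freq for r in self.records])

    def sha256(self) -> str:
        """Content hash of the canonical TSV serialisation (for manifests)."""
        return hashlib.sha256(_panel_to_tsv_text(self).encode()).hexdigest()


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the panel selection funnel.

    ``fdr_threshold=None`` disables the FDR stage (used when q-values for
    the candidate scan are not available).
    """

    gw_significance_threshold: float = 5e-8
    risk_or_min: float = 1.1
    protective_or_max: float = 0.9
    fdr_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gw_significance_threshold <= 1.0):
            raise ValidationError("gw_significance_threshold must be in (0,1]")
        if not self.risk_or_min > 1.0 > self.protective_or_max > 0.0:
            raise ValidationError("need risk_or_min > 1 > protective_or_max > 0")
        if self.fdr_threshold is not None and not (0.0 < self.fdr_threshold < 1.0):
            raise ValidationError("fdr_threshold must be in (0,1) or None")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j)``, capped
    at 1, returned in the input order.

    Raises
    ------
    ValidationError
        If the list is empty or any value lies outside (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValidationError("bh_fdr: empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValidationError("bh_fdr: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partition_candidates(
    candidates: Sequence[SnpRecord], criteria: SelectionCriteria
) -> tuple[list[SnpRecord], list[SnpRecord]]:
    """Split candidates into (kept, rejected) under ``criteria``.

    The FDR stage runs first (funnel order: FDR -> significance -> effect
    size); records without a stored ``fdr_q`` get one computed across the
    candidate list.  Input order is preserved in both outputs.
    """
    if not candidates:
        raise ValidationError("select_snps: no candidates supplied")
    cands = list(candidates)
    if criteria.fdr_threshold is not None and any(r.fdr_q is None for r in cands):
        qvals = bh_fdr([r.pvalue for r in cands])
        cands = [
            r if r.fdr_q is not None else replace(r, fdr_q=float(q))
            for r, q in zip(cands, qvals)
        ]
    kept: list[SnpRecord] = []
    rejected: list[SnpRecord] = []
    for rec in cands:
        ok = True
        if criteria.fdr_threshold is not None and rec.fdr_q > criteria.fdr_threshold:
            ok = False
        if rec.pvalue >= criteria.gw_significance_threshold:
            ok = False
        if not (
            rec.per_allele_or > criteria.risk_or_min
            or rec.per_allele_or < criteria.protective_or_max
        ):
            ok = False
        (kept if ok else rejected).append(rec)
    return kept, rejected


def select_snps(
    candidates: Sequence[SnpRecord], criteria: SelectionCriteria | None = None
) -> SnpPanel:
    """Apply the selection funnel and return the surviving panel.

    Raises :class:`EmptyPanelError` when no candidate survives (a score
    cannot be computed from an empty panel).
    """
    criteria = criteria or SelectionCriteria()
    kept, _ = partition_candidates(candidates, criteria)
    if not kept:
        raise EmptyPanelError(
            f"no candidate passed selection (of {len(candidates)} supplied)"
        )
    return SnpPanel.from_records(kept)


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    pvalue: float
    passed: bool
    monomorphic: bool = False


def hwe_check(
    genotype_counts: tuple[int, int, int], alpha: float = 0.05
) -> HweResult:
    """1-df asymptotic Hardy-Weinberg chi-square test on genotype counts.

    ``genotype_counts`` is ``(n_aa, n_ab, n_bb)`` where ``b`` is the allele
    whose homozygote is counted last; the test is symmetric in the labels.
    Expected counts come from the sample allele frequency.  A monomorphic
    locus passes with statistic 0 and a warning: it contributes a constant
    to every score, so equilibrium is vacuous.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValidationError("hwe_check: negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValidationError("hwe_check: total genotype count is zero")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p == 0.0 or p == 1.0:
        warnings.warn(
            "hwe_check: monomorphic locus, equilibrium test is vacuous",
            stacklevel=2,
        )
        return HweResult(0.0, 1.0, True, monomorphic=True)
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2, pval, passed=bool(pval >= alpha))


@dataclass(frozen=True)
class AllelicOrResult:
    """Per-allele odds ratio from logistic regression of status on dosage."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    flagged: bool = False
    reason: str | None = None

    @property
    def beta(self) -> float:
        return math.log(self.odds_ratio)


# |log OR| beyond this is treated as divergence of the ML fit (separation)
_SEPARATION_LOGOR = 15.0


def allelic_or(
    dosages: Sequence[float], status: Sequence[int]
) -> AllelicOrResult:
    """Per-allele OR with Wald 95% CI and p-value.

    Fits ``logit P(case) = a + beta * dosage`` by maximum likelihood on the
    collapsed 2x3 dosage-by-status table (identical likelihood to the
    per-subject fit, and much faster).  Missing dosages (NaN) are dropped.
    Perfect separation or a constant dosage yields a flagged result with an
    unbounded CI rather than a silent number.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    if d.shape != y.shape:
        raise ValidationError("allelic_or: dosages and status differ in length")
    keep = ~np.isnan(d)
    d, y = d[keep], y[keep]
    if d.size == 0:
        raise ValidationError("allelic_or: no observed dosages")
    if not np.all(np.isin(d, (0.0, 1.0, 2.0))):
        raise ValidationError("allelic_or: dosages must be 0, 1 or 2")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("allelic_or: status must be binary")
    if y.min() == y.max():
        raise ValidationError("allelic_or: need at least one case and one control")
    if d.min() == d.max():
        return AllelicOrResult(
            math.nan, math.nan, math.nan, math.nan,
            flagged=True, reason="no dosage variation",
        )

    # collapse to the 2x3 table and fit with frequency weights
    gg, yy, ww = [], [], []
    for g in (0.0, 1.0, 2.0):
        for s in (0.0, 1.0):
            w = int(np.sum((d == g) & (y == s)))
            if w:
                gg.append(g)
                yy.append(s)
                ww.append(w)
    X = sm.add_constant(np.asarray(gg), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(
            np.asarray(yy), X, family=sm.families.Binomial(),
            freq_weights=np.asarray(ww, dtype=float),
        ).fit(maxiter=200)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if abs(beta) > _SEPARATION_LOGOR or not np.isfinite(se):
        return AllelicOrResult(
            math.exp(min(max(beta, -700), 700)), 0.0, math.inf, math.nan,
            flagged=True, reason="perfect separation",
        )
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return AllelicOrResult(
        math.exp(beta), math.exp(lo), math.exp(hi), float(fit.pvalues[1])
    )


# ---------------------------------------------------------------------------
# panel TSV serialisation (tab-separated, fixed header, 15 significant digits)

_PANEL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele", "eaf", "or", "pvalue",
]


def _panel_to_tsv_text(panel: SnpPanel) -> str:
    lines = ["\t".join(_PANEL_COLUMNS)]
    for r in panel.records:
        lines.append(
            "\t".join(
                [
                    r.rsid,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    format(r.effect_allele_freq, ".17g"),
                    format(r.per_allele_or, ".17g"),
                    format(r.pvalue, ".17g"),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_panel_tsv(panel: SnpPanel, path) -> None:
    """Write the panel as TSV (17 significant digits: exact float round-trip)."""
    with open(path, "w") as fh:
        fh.write(_panel_to_tsv_text(panel))


def read_panel_tsv(path) -> SnpPanel:
    """Read a panel TSV written by :func:`write_panel_tsv` (or compatible)."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str},
                     float_precision="round_trip")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: panel TSV missing columns {missing}")
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            records.append(
                SnpRecord(
                    rsid=str(row["rsid"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    effect_allele_freq=float(row["eaf"]),
                    per_allele_or=float(row["or"]),
                    pvalue=float(row["pvalue"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return SnpPanel.from_records(records)


def load_default_panel() -> SnpPanel:
    """The packaged 55-locus demonstration panel.

    A synthetic stand-in for a population-specific prostate-cancer panel:
    47 risk loci (OR 1.11-1.18) and 8 protective loci (OR 0.85-0.89) with
    effect-allele frequencies tuned so the log-risk variance under
    Hardy-Weinberg independence is sigma^2 = 0.180, i.e. a theoretical
    case-control AUC of 0.618 under the multiplicative model.
    """
    ref = resources.files("finnprs.data").joinpath("synthetic_panel55.tsv")
    with resources.as_file(ref) as path:
        return read_panel_tsv(path)
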