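"""Polygenic risk score computation and multiplicative-model parameters.

The score of subject ``j`` is the weighted allele count

    PRS_j = sum_i beta_i * x_ij,

where ``beta_i = ln(OR_i)`` and ``x_ij`` in {0, 1, 2} is the effect-allele
dosage.  Under Hardy-Weinberg equilibrium and independent loci the
population log-relative-risk is approximately normal with variance

    sigma^2 = sum_i 2 p_i (1 - p_i) beta_i^2

and, on the relative-risk scale, the convention mu = -sigma^2/2 centres the
population mean relative risk at one.  All evaluation downstream runs on
raw scores; centring to the mu convention is an explicit, separate step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

from .cohort import GenotypeMatrix
from .exceptions import MissingSnpError, ValidationError
from .panel import SnpPanel

__all__ = [
    "PrsResult",
    "NormalityCheck",
    "compute_prs",
    "population_params",
    "expected_raw_mean",
    "standardize_scores",
    "theoretical_auc",
]

MissingMode = Literal["mean_impute", "omit"]


@dataclass(frozen=True)
class PrsResult:
    """Per-subject scores plus the panel's population parameters."""

    subject_ids: tuple[str, ...]
    scores: np.ndarray
    n_loci_used: np.ndarray
    population_mu: float
    population_sigma2: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores must be finite")
        if self.population_sigma2 < 0:
            raise ValidationError("population_sigma2 must be >= 0")


@dataclass(frozen=True)
class NormalityCheck:
    """D'Agostino-Pearson omnibus normality test on a score vector."""

    statistic: float
    pvalue: float
    normal_at_05: bool


def population_params(panel: SnpPanel) -> tuple[float, float]:
    """(mu, sigma^2) of the population log-relative-risk.

    sigma^2 = sum_i 2 p_i (1-p_i) beta_i^2 under HWE and locus
    independence; mu = -sigma^2 / 2.
    """
    p = panel.effect_allele_freqs
    b = panel.weights
    sigma2 = float(np.sum(2.0 * p * (1.0 - p) * b**2))
    return -sigma2 / 2.0, sigma2


def expected_raw_mean(panel: SnpPanel) -> float:
    """Population mean of the raw score, ``sum_i 2 p_i beta_i`` (HWE)."""
    return float(np.sum(2.0 * panel.effect_allele_freqs * panel.weights))


def compute_prs(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    missing_mode: MissingMode = "mean_impute",
) -> PrsResult:
    """Raw polygenic risk scores for every subject.

    Missing dosages are mean-imputed with the HWE expectation ``2 p_i``
    (default, keeps scores comparable across subjects) or the locus is
    omitted from the sum (``missing_mode="omit"``).  ``n_loci_used`` counts
    observed (non-missing) loci either way.

    Raises
    ------
    MissingSnpError
        If any panel SNP is absent from the genotype matrix.
    """
    if missing_mode not in ("mean_impute", "omit"):
        raise ValidationError(f"unknown missing_mode {missing_mode!r}")
    col = {s: i for i, s in enumerate(genotypes.snp_ids)}
    absent = [r for r in panel.rsids if r not in col]
    if absent:
        raise MissingSnpError(absent)
    idx = [col[r] for r in panel.rsids]
    d = genotypes.dosages[:, idx]
    observed = ~np.isnan(d)
    n_used = observed.sum(axis=1)
    beta = panel.weights
    if missing_mode == "mean_impute":
        fill = 2.0 * panel.effect_allele_freqs
        d = np.where(observed, d, fill)
    else:
        d = np.where(observed, d, 0.0)
    scores = d @ beta
    mu, sigma2 = population_params(panel)
    return PrsResult(genotypes.subject_ids, scores, n_used, mu, sigma2)


def standardize_scores(
    result: PrsResult,
    panel: SnpPanel,
    log_transform: bool = False,
    control_mask: np.ndarray | None = None,
) -> tuple[PrsResult, NormalityCheck]:
    """Centre raw scores to the mu = -sigma^2/2 convention.

    Scores are shifted by ``mu - E[raw]`` with ``E[raw] = sum 2 p_i beta_i``,
    so the population-mean log relative risk is -sigma^2/2 and the mean
    relative risk exp(score) is one.  A D'Agostino-Pearson normality check
    is reported on the controls when ``control_mask`` is given, else on all
    subjects.

    ``log_transform=True`` applies the monotone shift-log transform
    ``ln(score - min(score) + 1)`` to the raw scores *instead* of centring;
    it is never applied implicitly.
    """
    raw = result.scores
    if log_transform:
        new = np.log(raw - raw.min() + 1.0)
    else:
        shift = result.population_mu - expected_raw_mean(panel)
        new = raw + shift
    checked = new if control_mask is None else new[np.asarray(control_mask, bool)]
    if checked.size >= 20 and np.ptp(checked) > 0:
        stat, pval = stats.normaltest(checked)
        check = NormalityCheck(float(stat), float(pval), bool(pval >= 0.05))
    else:  # too few values for the omnibus test to be meaningful
        check = NormalityCheck(float("nan"), float("nan"), False)
    return replace(result, scores=new), check


def theoretical_auc(sigma2: float) -> float:
    """Model-implied ROC AUC, ``Phi(sigma / sqrt(2))``.

    Under the multiplicative model the control log-risk is N(mu, sigma^2)
    and the case distribution is the exponential tilt, N(mu + sigma^2,
    sigma^2); the AUC of two equal-variance normals separated by sigma^2
    is Phi(sigma / sqrt 2).
    """
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    return float(stats.norm.cdf(np.sqrt(sigma2 / 2.0)))
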