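"""Screening-cohort analysis: PRS quartiles vs PSA, and PSA/age/PRS models.

Within a screening-trial cohort (cancer-free controls plus screen-detected
cases) two questions are asked of the score:

1. Does the fraction of men with an elevated PSA (>= 4 ng/mL) rise across
   PRS quartiles?  (quartile x PSA-positivity table with a Pearson
   chi-square)
2. Does the PRS add predictive information beyond PSA and age?  (simple
   one-covariate logistic models and a mutually adjusted multiple model,
   with the cumulative AUC as covariates are added PSA -> age -> PRS)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import LogisticFit, chi_square_independence, logistic_fit
from .exceptions import ValidationError

__all__ = ["PsaQuartileTable", "ScreeningModelReport", "psa_quartile_table",
           "finrspc_models"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsaQuartileTable:
    """PSA positivity within quartiles of the polygenic risk score."""

    threshold: float
    quartile_n: tuple[int, int, int, int]
    n_negative: tuple[int, int, int, int]
    n_positive: tuple[int, int, int, int]
    pct_positive: tuple[float, float, float, float]
    chi_square: float
    pvalue: float
    n_excluded_missing_psa: int = 0

    @classmethod
    def from_counts(
        cls,
        negative: tuple[int, int, int, int],
        positive: tuple[int, int, int, int],
        threshold: float = 4.0,
    ) -> "PsaQuartileTable":
        """Build the table from per-quartile (PSA<thr, PSA>=thr) counts."""
        neg = tuple(int(x) for x in negative)
        pos = tuple(int(x) for x in positive)
        qn = tuple(a + b for a, b in zip(neg, pos))
        if min(qn) == 0:
            raise ValidationError("PsaQuartileTable: empty quartile")
        pct = tuple(100.0 * p / n for p, n in zip(pos, qn))
        chi2, _, pval = chi_square_independence(np.column_stack([neg, pos]))
        return cls(threshold, qn, neg, pos, pct, chi2, pval)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quartile": ["Q1", "Q2", "Q3", "Q4"],
                "n": self.quartile_n,
                "psa_below": self.n_negative,
                "psa_at_or_above": self.n_positive,
                "pct_positive": self.pct_positive,
            }
        )


def psa_quartile_table(
    prs_scores, psa_values, threshold: float = 4.0
) -> PsaQuartileTable:
    """Cross-tabulate PRS quartiles against PSA positivity.

    Quartiles are linear-interpolation empirical quartiles of the PRS in
    the analysed cohort itself; positive means PSA >= ``threshold``.
    Subjects with missing PSA are excluded, with the count logged and
    carried in the result (no silent loss).
    """
    prs = np.asarray(prs_scores, dtype=float)
    psa = np.asarray(psa_values, dtype=float)
    if prs.shape != psa.shape:
        raise ValidationError("psa_quartile_table: misaligned inputs")
    keep = np.isfinite(psa)
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("psa_quartile_table: excluded %d subjects with missing PSA",
                    n_excluded)
    prs, psa = prs[keep], psa[keep]
    if np.any(psa <= 0):
        raise ValidationError("psa_quartile_table: PSA values must be positive")
    if prs.size < 8:
        raise ValidationError("psa_quartile_table: need >= 8 subjects")
    bounds = np.quantile(prs, [0.25, 0.5, 0.75])
    bins = (prs[:, None] > bounds[None, :]).sum(axis=1)
    pos_flag = psa >= threshold
    neg = tuple(int(np.sum((bins == k) & ~pos_flag)) for k in range(4))
    pos = tuple(int(np.sum((bins == k) & pos_flag)) for k in range(4))
    table = PsaQuartileTable.from_counts(neg, pos, threshold)
    if n_excluded:
        table = PsaQuartileTable(
            table.threshold, table.quartile_n, table.n_negative,
            table.n_positive, table.pct_positive, table.chi_square,
            table.pvalue, n_excluded,
        )
    return table


@dataclass(frozen=True)
class ScreeningModelReport:
    """Simple and multiple logistic models for PSA, age and PRS."""

    factors: tuple[str, str, str]
    simple_fits: dict[str, LogisticFit]
    multiple_fit: LogisticFit
    cumulative_fits: tuple[LogisticFit, ...]

    @property
    def cumulative_auc(self) -> tuple[float, ...]:
        return tuple(f.model_auc for f in self.cumulative_fits)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.factors):
            s = self.simple_fits[f].term(f)
            m = self.multiple_fit.term(f)
            rows.append(
                {
                    "factor": f,
                    "simple_or": s["or"],
                    "simple_ci_low": s["ci"][0],
                    "simple_ci_high": s["ci"][1],
                    "simple_p": s["p"],
                    "simple_auc": self.simple_fits[f].model_auc,
                    "multiple_or": m["or"],
                    "multiple_ci_low": m["ci"][0],
                    "multiple_ci_high": m["ci"][1],
                    "multiple_p": m["p"],
                    "cumulative_auc": self.cumulative_auc[i],
                }
            )
        return pd.DataFrame(rows)


def finrspc_models(status, psa, age, prs) -> ScreeningModelReport:
    """Screening-cohort prediction models with PSA, age and PRS.

    All covariates enter untransformed and continuous.  Fits three simple
    (one-covariate) models, the mutually adjusted multiple model, and the
    cumulative sequence PSA -> PSA+age -> PSA+age+PRS whose in-sample AUC
    is non-decreasing.  Quasi-separated fits arrive flagged by
    :func:`finnprs.evaluate.logistic_fit`; they are reported, not hidden.
    """
    y = np.asarray(status, dtype=float)
    cov = {
        "psa": np.asarray(psa, dtype=float),
        "age": np.asarray(age, dtype=float),
        "prs": np.asarray(prs, dtype=float),
    }
    for name, v in cov.items():
        if v.shape != y.shape:
            raise ValidationError(f"finrspc_models: {name} misaligned with status")
    simple = {name: logistic_fit(y, {name: v}) for name, v in cov.items()}
    multiple = logistic_fit(y, cov)
    cumulative = (
        simple["psa"],
        logistic_fit(y, {k: cov[k] for k in ("psa", "age")}),
        multiple,
    )
    aucs = [f.model_auc for f in cumulative]
    if not all(b >= a - 1e-6 for a, b in zip(aucs, aucs[1:])):
        logger.warning("finrspc_models: cumulative AUC decreased beyond tolerance: %s",
                       aucs)
    return ScreeningModelReport(("psa", "age", "prs"), simple, multiple, cumulative)
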