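"""Synthetic case-control cohorts under the multiplicative risk model.

Controls are drawn locus-by-locus from Hardy-Weinberg proportions at the
panel allele frequencies.  Cases are drawn from the exponentially tilted
genotype law ``P(g | case) proportional to OR^g * P_HWE(g)`` — the exact
case genotype distribution implied by a multiplicative (log-additive)
per-allele relative risk under the rare-disease approximation.  Tilting a
Binomial(2, p) by ``OR^g`` is again binomial, at the tilted allele
frequency

    p' = p * OR / (1 - p + p * OR),

which gives both an O(n*m) sampler and closed-form oracles for tests.

Clinical phenotypes (age, PSA, Gleason grade, TNM stage, cause of death)
are drawn independently of the genotypes from configurable categorical
marginals whose defaults reproduce the baseline characteristics of a
Finnish non-familial prostate-cancer case series (clinically detected and
screen-detected columns).  Baseline PSA for screening-cohort subjects is
log-normal, with the case distribution shifted so a 4 ng/mL threshold has
~90% case sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .panel import SnpPanel

__all__ = [
    "GenotypeMatrix",
    "PsaModel",
    "SimConfig",
    "DEFAULT_MARGINALS",
    "PHENOTYPE_COLUMNS",
    "tilted_allele_freq",
    "tilted_genotype_probs",
    "expected_case_control_score_shift",
    "simulate_controls",
    "simulate_cases",
    "inject_missingness",
    "attach_phenotypes",
    "simulate_cohort",
]

# named sub-streams derived from the master seed, so each stage is
# independently reproducible: rng = default_rng(SeedSequence([seed, id]))
_STREAMS = {"controls": 1, "cases": 2, "missing": 3, "phenotypes": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValidationError("seed must be a non-negative integer")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects-by-SNPs effect-allele dosage matrix.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing.
    """

    subject_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = self.dosages
        if d.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValidationError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids")
        vals = d[~np.isnan(d)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValidationError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=list(self.subject_ids), columns=list(self.snp_ids)
        )

    @classmethod
    def concat(cls, *parts: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack cohorts subject-wise; all parts must share the SNP list."""
        snp_ids = parts[0].snp_ids
        for p in parts[1:]:
            if p.snp_ids != snp_ids:
                raise ValidationError("cannot concat: SNP lists differ")
        ids = tuple(s for p in parts for s in p.subject_ids)
        return cls(ids, snp_ids, np.vstack([p.dosages for p in parts]))


def tilted_allele_freq(p: float, odds_ratio: float) -> float:
    """Effect-allele frequency among cases, ``p*OR / (1 - p + p*OR)``."""
    return p * odds_ratio / (1.0 - p + p * odds_ratio)


def tilted_genotype_probs(p: float, odds_ratio: float) -> np.ndarray:
    """Case genotype probabilities (g = 0, 1, 2) under the tilted law."""
    q = tilted_allele_freq(p, odds_ratio)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def expected_case_control_score_shift(panel: SnpPanel) -> float:
    """Exact mean raw-score difference, cases minus controls.

    ``sum_i 2 * beta_i * (p'_i - p_i)`` from the tilted law; for small
    weights this approaches the log-risk variance sigma^2.
    """
    p = panel.effect_allele_freqs
    b = panel.weights
    q = np.array([tilted_allele_freq(r.effect_allele_freq, r.per_allele_or)
                  for r in panel.records])
    return float(np.sum(2.0 * b * (q - p)))


def _simulate(panel: SnpPanel, n: int, rng: np.random.Generator,
              freqs: np.ndarray, prefix: str) -> GenotypeMatrix:
    if n <= 0:
        raise ValidationError("number of subjects must be positive")
    dosages = rng.binomial(2, freqs, size=(n, len(panel))).astype(float)
    ids = tuple(f"{prefix}{i:06d}" for i in range(1, n + 1))
    return GenotypeMatrix(ids, tuple(panel.rsids), dosages)


def simulate_controls(
    panel: SnpPanel, n: int, seed: int, id_prefix: str = "ctrl"
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes at the panel allele frequencies."""
    return _simulate(panel, n, _rng(seed, "controls"),
                     panel.effect_allele_freqs, id_prefix)


def simulate_cases(
    panel: SnpPanel, n: int, seed: int, id_prefix: str = "case"
) -> GenotypeMatrix:
    """Case genotypes from the per-locus tilted law (loci independent)."""
    q = np.array([tilted_allele_freq(r.effect_allele_freq, r.per_allele_or)
                  for r in panel.records])
    return _simulate(panel, n, _rng(seed, "cases"), q, id_prefix)


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each dosage missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValidationError("missing rate must be in [0, 1)")
    if rate == 0.0:
        return genotypes
    mask = _rng(seed, "missing").random(genotypes.dosages.shape) < rate
    dosages = genotypes.dosages.copy()
    dosages[mask] = np.nan
    return GenotypeMatrix(genotypes.subject_ids, genotypes.snp_ids, dosages)


# ---------------------------------------------------------------------------
# clinical phenotypes

PHENOTYPE_COLUMNS = [
    "subject_id", "is_case", "source", "age_at_diagnosis", "age_baseline",
    "psa_at_diagnosis", "psa_baseline", "gleason",
    "t_stage", "n_stage", "m_stage", "death_cause",
]

_MISSING = "missing"


def _norm(d: dict[str, float]) -> dict[str, float]:
    # printed percentage columns can sum to 100.1 from rounding; renormalise
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


# Baseline clinical marginals of non-familial prostate-cancer patients,
# clinically detected vs screen-detected columns (fractions incl. a
# "missing" category where the source table reports one).
DEFAULT_MARGINALS: dict[str, dict[str, dict[str, float]]] = {
    "clinical": {
        "age": _norm({"early": 4.5, "late": 95.5}),
        "psa_dx": _norm({"low": 73.8, "high": 19.9, _MISSING: 6.3}),
        "gleason": _norm({"le6": 45.3, "7": 24.7, "ge8": 14.4, _MISSING: 15.6}),
        "t_stage": _norm({"T0/Tx": 0.0, "T1": 32.8, "T2": 40.3,
                          "T3": 18.3, "T4": 4.2, _MISSING: 4.4}),
        "n_stage": _norm({"N0/Nx": 95.0, "N1": 0.6, _MISSING: 4.4}),
        "m_stage": _norm({"M0/Mx": 87.6, "M1": 8.0, _MISSING: 4.4}),
        "death": _norm({"PC": 13.0, "other": 37.9, "alive": 49.2}),
    },
    "screening_trial": {
        "age": _norm({"early": 0.7, "late": 99.3}),
        "psa_dx": _norm({"low": 91.2, "high": 6.4, _MISSING: 2.4}),
        "gleason": _norm({"le6": 63.1, "7": 26.6, "ge8": 8.6, _MISSING: 1.8}),
        "t_stage": _norm({"T0/Tx": 2.9, "T1": 78.9, "T2": 11.0,
                          "T3": 5.5, "T4": 0.2, _MISSING: 1.5}),
        "n_stage": _norm({"N0/Nx": 98.2, "N1": 0.2, _MISSING: 1.5}),
        "m_stage": _norm({"M0/Mx": 96.7, "M1": 1.8, _MISSING: 1.5}),
        "death": _norm({"PC": 1.76, "other": 13.9, "alive": 84.4}),
    },
}

_Z90 = 1.2815515655446004  # standard normal 90th percentile


@dataclass(frozen=True)
class PsaModel:
    """Log-normal baseline PSA (ng/mL) for screening-cohort subjects.

    Control parameters give ~2% of healthy men a PSA >= 4 ng/mL; the case
    log-mean is ``ln 4 + z_0.90 * sd`` so that the conventional 4 ng/mL
    screening threshold detects ~90% of cases.
    """

    control_log_mean: float = math.log(1.1)
    control_log_sd: float = 0.7
    case_log_mean: float = math.log(4.0) + _Z90 * 0.9
    case_log_sd: float = 0.9
    threshold: float = 4.0

    def __post_init__(self) -> None:
        if self.control_log_sd <= 0 or self.case_log_sd <= 0:
            raise ValidationError("PSA log-sd parameters must be positive")


@dataclass
class SimConfig:
    """Full description of one synthetic study cohort.

    Defaults mirror the study layout the analysis expects: 2,283 clinically
    detected cases, 455 screen-detected cases and 2,400 cancer-free
    screening-trial controls, genotyped on a 55-locus panel.
    """

    panel: SnpPanel
    n_clinical_cases: int = 2283
    n_screening_cases: int = 455
    n_controls: int = 2400
    seed: int = 0
    missing_rate: float = 0.0
    clinical_marginals: Mapping = dc_field(
        default_factory=lambda: DEFAULT_MARGINALS)
    psa_model: PsaModel = dc_field(default_factory=PsaModel)
    # optional log-odds of M1 stage per case PRS standard deviation
    m1_prs_log_or: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_clinical_cases, self.n_screening_cases) < 0:
            raise ValidationError("case counts must be non-negative")
        if self.n_controls < 0 or self.n_cases + self.n_controls == 0:
            raise ValidationError("cohort must contain subjects")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        for src, fields in self.clinical_marginals.items():
            for name, probs in fields.items():
                s = sum(probs.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValidationError(
                        f"marginals[{src}][{name}] sum to {s}, expected 1"
                    )
                if any(v < 0 for v in probs.values()):
                    raise ValidationError(
                        f"marginals[{src}][{name}] contain negative probability"
                    )

    @property
    def n_cases(self) -> int:
        return self.n_clinical_cases + self.n_screening_cases


def _draw(rng, probs: dict[str, float], n: int) -> np.ndarray:
    cats = list(probs)
    return rng.choice(cats, size=n, p=[probs[c] for c in cats])


def _gleason_numeric(rng, cat: str) -> float:
    if cat == "le6":
        return float(rng.choice([5, 6], p=[0.15, 0.85]))
    if cat == "7":
        return 7.0
    if cat == "ge8":
        return float(rng.choice([8, 9, 10], p=[0.60, 0.30, 0.10]))
    return np.nan


def attach_phenotypes(genotypes: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Draw clinical phenotypes for a simulated cohort.

    The genotype matrix must be ordered clinical cases, then screening-trial
    cases, then controls, with row counts matching ``config``.  Clinical
    covariates are independent of the genotypes given case status, except
    for an optional M1-stage log-odds tilt per PRS standard deviation
    (``config.m1_prs_log_or``, default 0).

    Returns a :data:`PHENOTYPE_COLUMNS` data frame; ``m_stage`` and the
    other staging fields use pandas missing values where the source
    marginals have a missing category.
    """
    n_total = config.n_cases + config.n_controls
    if genotypes.n_subjects != n_total:
        raise ValidationError(
            f"genotypes have {genotypes.n_subjects} subjects, "
            f"config expects {n_total}"
        )
    rng = _rng(config.seed, "phenotypes")
    source = np.array(
        ["clinical"] * config.n_clinical_cases
        + ["screening_trial"] * config.n_screening_cases
        + ["control"] * config.n_controls
    )
    is_case = source != "control"
    n = n_total

    age_dx = np.full(n, np.nan)
    age_base = np.full(n, np.nan)
    psa_dx = np.full(n, np.nan)
    psa_base = np.full(n, np.nan)
    gleason = np.full(n, np.nan)
    t_stage = np.array([None] * n, dtype=object)
    n_stage = np.array([None] * n, dtype=object)
    m_stage = np.array([None] * n, dtype=object)
    death = np.array([None] * n, dtype=object)

    # optional PRS-linked M1 tilt needs case scores in SD units
    z_prs = np.zeros(n)
    if config.m1_prs_log_or != 0.0 and is_case.any():
        from .score import compute_prs  # local import avoids a module cycle

        scores = compute_prs(genotypes, config.panel).scores
        cs = scores[is_case]
        sd = cs.std() or 1.0
        z_prs = (scores - cs.mean()) / sd

    for src in ("clinical", "screening_trial"):
        idx = np.flatnonzero(source == src)
        if idx.size == 0:
            continue
        marg = config.clinical_marginals[src]

        cat = _draw(rng, marg["age"], idx.size)
        age_dx[idx] = np.where(
            cat == "early", rng.uniform(44.0, 55.0, idx.size),
            rng.uniform(56.0, 75.0, idx.size),
        )

        cat = _draw(rng, marg["psa_dx"], idx.size)
        low = np.exp(rng.normal(math.log(6.0), 0.8, idx.size))
        low = np.minimum(low, 19.9)  # truncate the "low" stratum at 20 ng/mL
        high = 20.0 + np.exp(rng.normal(math.log(10.0), 1.0, idx.size))
        psa_dx[idx] = np.where(cat == "low", low,
                               np.where(cat == "high", high, np.nan))

        cat = _draw(rng, marg["gleason"], idx.size)
        gleason[idx] = [_gleason_numeric(rng, c) for c in cat]

        for fieldname, out in (("t_stage", t_stage), ("n_stage", n_stage)):
            cat = _draw(rng, marg[fieldname], idx.size)
            out[idx] = np.where(cat == _MISSING, None, cat)

        mprobs = marg["m_stage"]
        if config.m1_prs_log_or == 0.0:
            cat = _draw(rng, mprobs, idx.size)
            m_stage[idx] = np.where(cat == _MISSING, None, cat)
        else:
            p_miss = mprobs.get(_MISSING, 0.0)
            base_odds = mprobs["M1"] / mprobs["M0/Mx"]
            # divide by E[exp(b Z)] = e^{b^2/2} so the tilt (approximately)
            # preserves the configured marginal M1 rate
            b = config.m1_prs_log_or
            odds = base_odds * np.exp(b * z_prs[idx] - b * b / 2.0)
            p1 = (1.0 - p_miss) * odds / (1.0 + odds)
            u = rng.random(idx.size)
            m_stage[idx] = np.where(
                u < p_miss, None, np.where(u < p_miss + p1, "M1", "M0/Mx")
            )

        death[idx] = _draw(rng, marg["death"], idx.size)

    # FinRSPC-style baseline measurements for screening-arm subjects
    pm = config.psa_model
    finr = np.flatnonzero(source != "clinical")
    age_base[finr] = rng.uniform(55.0, 67.0, finr.size)
    for which, mu, sd in (
        (True, pm.case_log_mean, pm.case_log_sd),
        (False, pm.control_log_mean, pm.control_log_sd),
    ):
        idx = np.flatnonzero((source != "clinical") & (is_case == which))
        psa_base[idx] = np.exp(rng.normal(mu, sd, idx.size))

    death[source == "control"] = "alive"

    df = pd.DataFrame(
        {
            "subject_id": list(genotypes.subject_ids),
            "is_case": is_case,
            "source": source,
            "age_at_diagnosis": age_dx,
            "age_baseline": age_base,
            "psa_at_diagnosis": psa_dx,
            "psa_baseline": psa_base,
            "gleason": pd.array(
                [int(g) if np.isfinite(g) else None for g in gleason],
                dtype="Int64",
            ),
            "t_stage": t_stage,
            "n_stage": n_stage,
            "m_stage": m_stage,
            "death_cause": death,
        }
    )
    return df


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes plus phenotypes for a full synthetic study cohort.

    Cases (clinical then screening-trial) precede controls in the subject
    order.  Missingness, if configured, is injected after phenotype
    assignment so phenotypes never depend on the missingness mask.
    """
    parts = []
    if config.n_cases > 0:
        parts.append(simulate_cases(config.panel, config.n_cases, config.seed))
    if config.n_controls > 0:
        parts.append(simulate_controls(config.panel, config.n_controls, config.seed))
    genotypes = GenotypeMatrix.concat(*parts)
    phenotypes = attach_phenotypes(genotypes, config)
    if config.missing_rate > 0:
        genotypes = inject_missingness(genotypes, config.missing_rate, config.seed)
    return genotypes, phenotypes
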