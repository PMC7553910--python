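"""End-to-end pipeline: simulate -> score -> evaluate -> screening model.

Every stage logs one structured line with its input/output row counts, and
all emitted numbers land both in TSV tables (human-readable) and one JSON
report (machine-readable, deterministic byte-for-byte for a fixed config).
A run manifest records the seed, panel hash and package versions needed to
reproduce the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SimConfig, simulate_cohort
from .evaluate import (
    DiagnosticSummary,
    median_cutoff_summary,
    quartile_stratification,
    roc_auc,
    subgroup_summary,
)
from .exceptions import FinnPrsError, ValidationError
from .io import (
    read_genotypes,
    read_phenotypes_csv,
    write_dosage_tsv,
    write_phenotypes_csv,
    write_scores,
)
from .panel import load_default_panel, read_panel_tsv
from .score import compute_prs, theoretical_auc
from .screening import finrspc_models, psa_quartile_table

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# case subgroups analysed case-only against the control-median cutoff
_SUBGROUPS = [
    ("high_psa_dx", lambda ph: ph["psa_at_diagnosis"] > 20.0),
    ("gleason_ge8", lambda ph: ph["gleason"].fillna(-1).astype(float) >= 8),
    ("advanced_stage", lambda ph: (
        ph["t_stage"].isin(["T3", "T4"])
        | (ph["n_stage"] == "N1")
        | (ph["m_stage"] == "M1")
    )),
    ("death_pc", lambda ph: ph["death_cause"] == "PC"),
    ("t3_t4", lambda ph: ph["t_stage"].isin(["T3", "T4"])),
    ("n1", lambda ph: ph["n_stage"] == "N1"),
    ("m1", lambda ph: ph["m_stage"] == "M1"),
]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    # simulation block (used when simulate=True)
    n_clinical_cases: int = 2283
    n_screening_cases: int = 455
    n_controls: int = 2400
    missing_rate: float = 0.0
    # inputs (used when simulate=False)
    panel_path: str | None = None  # None -> packaged 55-locus panel
    genotypes_path: str | None = None
    genotypes_format: str = "dosage_tsv"
    phenotypes_path: str | None = None
    # analysis options
    missing_mode: str = "mean_impute"
    quartile_basis: str = "pooled"
    auc_ci_method: str = "hanley"
    log_transform: bool = False
    psa_threshold: float = 4.0

    def __post_init__(self) -> None:
        if self.quartile_basis not in ("pooled", "controls"):
            raise ValidationError(f"unknown quartile_basis {self.quartile_basis!r}")
        if self.auc_ci_method not in ("hanley", "delong"):
            raise ValidationError(f"unknown auc_ci_method {self.auc_ci_method!r}")
        if self.missing_mode not in ("mean_impute", "omit"):
            raise ValidationError(f"unknown missing_mode {self.missing_mode!r}")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        if not self.simulate:
            for name in ("genotypes_path", "phenotypes_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(
                        f"simulate=False requires {name} to be set"
                    )
                if not Path(p).exists():
                    raise ValidationError(f"{name}: no such file {p}")
        if self.panel_path is not None and not Path(self.panel_path).exists():
            raise ValidationError(f"panel_path: no such file {self.panel_path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _diag_dict(d: DiagnosticSummary) -> dict:
    return {
        "cutoff": d.cutoff, "tp": d.tp, "fn": d.fn, "fp": d.fp, "tn": d.tn,
        "sensitivity": d.sensitivity, "specificity": d.specificity,
        "ppv": d.ppv, "npv": d.npv, "lr_positive": d.lr_positive,
        "odds_ratio": d.odds_ratio, "or_ci": list(d.or_ci),
        "or_pvalue": d.or_pvalue,
    }


def _group_summary(scores: np.ndarray) -> dict:
    n = scores.size
    se = float(scores.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "n": int(n),
        "mean": float(scores.mean()),
        "se_mean": se,
        "median": float(np.median(scores)),
        "variance": float(scores.var(ddof=1)) if n > 1 else float("nan"),
        "sd": float(scores.std(ddof=1)) if n > 1 else float("nan"),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle under ``out_dir``.

    Returns the JSON-ready report dictionary.  Any stage failure raises a
    :class:`FinnPrsError` tagged with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = (read_panel_tsv(config.panel_path) if config.panel_path
             else load_default_panel())
    logger.info("stage=panel n_loci=%d", len(panel))

    # ------------------------------------------------------------- stage 1
    try:
        if config.simulate:
            sim = SimConfig(
                panel=panel,
                n_clinical_cases=config.n_clinical_cases,
                n_screening_cases=config.n_screening_cases,
                n_controls=config.n_controls,
                seed=config.seed,
                missing_rate=config.missing_rate,
            )
            genotypes, phenotypes = simulate_cohort(sim)
            write_dosage_tsv(genotypes, out / "genotypes.tsv")
            write_phenotypes_csv(phenotypes, out / "phenotypes.csv")
        else:
            genotypes = read_genotypes(
                config.genotypes_path, config.genotypes_format, panel
            )
            phenotypes = read_phenotypes_csv(config.phenotypes_path)
            if list(phenotypes["subject_id"]) != list(genotypes.subject_ids):
                raise ValidationError(
                    "phenotype subject order does not match genotypes"
                )
    except FinnPrsError as exc:
        raise FinnPrsError(f"stage=cohort: {exc}") from exc
    logger.info(
        "stage=cohort subjects=%d snps=%d cases=%d",
        genotypes.n_subjects, genotypes.n_snps, int(phenotypes["is_case"].sum()),
    )

    # ------------------------------------------------------------- stage 2
    try:
        prs = compute_prs(genotypes, panel, missing_mode=config.missing_mode)
        write_scores(prs, panel, out / "scores.tsv",
                     missing_mode=config.missing_mode)
    except FinnPrsError as exc:
        raise FinnPrsError(f"stage=score: {exc}") from exc
    logger.info("stage=score subjects=%d sigma2=%.4f",
                len(prs.subject_ids), prs.population_sigma2)

    # ------------------------------------------------------------- stage 3
    try:
        report = _evaluate_stage(prs, phenotypes, config)
    except FinnPrsError as exc:
        raise FinnPrsError(f"stage=evaluate: {exc}") from exc

    # ------------------------------------------------------------- stage 4
    try:
        report["screening"] = _screening_stage(prs, phenotypes, config)
    except FinnPrsError as exc:
        raise FinnPrsError(f"stage=screen: {exc}") from exc

    report["manifest"] = {
        "finnprs_version": __version__,
        "seed": config.seed,
        "panel_sha256": panel.sha256(),
        "n_loci": len(panel),
        # out_dir does not affect any number; excluding it keeps the
        # report byte-identical across output locations
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k != "out_dir"
        },
    }
    _write_reports(report, out)
    logger.info("stage=report out_dir=%s", out)
    return report


def _evaluate_stage(prs, phenotypes: pd.DataFrame, config: PipelineConfig) -> dict:
    scores = prs.scores
    is_case = phenotypes["is_case"].to_numpy(bool)
    source = phenotypes["source"].to_numpy()
    case_scores = scores[is_case]
    ctrl_scores = scores[~is_case]

    groups = {
        "study_population": _group_summary(scores),
        "controls": _group_summary(ctrl_scores),
        "all_cases": _group_summary(case_scores),
        "screening_trial_cases": _group_summary(scores[source == "screening_trial"]),
        "clinical_cases": _group_summary(scores[source == "clinical"]),
    }

    overall = median_cutoff_summary(case_scores, ctrl_scores)
    cutoff = overall.cutoff
    risk_rows = {"all_cases": _diag_dict(overall)}
    for label, sel in (
        ("clinical_cases", source == "clinical"),
        ("screening_trial_cases", source == "screening_trial"),
    ):
        if (sel & is_case).any():
            risk_rows[label] = _diag_dict(
                median_cutoff_summary(scores[sel & is_case], ctrl_scores)
            )

    roc_all = roc_auc(case_scores, ctrl_scores, ci_method=config.auc_ci_method)
    roc_rows = {
        "all_cases": {"auc": roc_all.auc, "ci": list(roc_all.ci95),
                      "p_vs_half": roc_all.pvalue_vs_half}
    }
    for label, sel in (
        ("clinical_cases", source == "clinical"),
        ("screening_trial_cases", source == "screening_trial"),
    ):
        if (sel & is_case).any():
            r = roc_auc(scores[sel & is_case], ctrl_scores,
                        ci_method=config.auc_ci_method)
            roc_rows[label] = {"auc": r.auc, "ci": list(r.ci95),
                               "p_vs_half": r.pvalue_vs_half}

    cases_ph = phenotypes.loc[is_case]
    subgroups = {}
    for name, pred in _SUBGROUPS:
        flag = pred(cases_ph).to_numpy(bool)
        if flag.any() and not flag.all():
            s = subgroup_summary(case_scores, flag, cutoff)
            subgroups[name] = {
                "n": s.n_subgroup, "n_above": s.n_above,
                "pct_above": 100.0 * s.frac_above,
                "odds_ratio": s.odds_ratio, "or_ci": list(s.or_ci),
                "or_pvalue": s.or_pvalue, "auc": s.auc,
                "auc_ci": list(s.auc_ci),
            }

    quart = quartile_stratification(case_scores, ctrl_scores,
                                    basis=config.quartile_basis)
    logger.info(
        "stage=evaluate cases=%d controls=%d auc=%.3f",
        case_scores.size, ctrl_scores.size, roc_all.auc,
    )
    return {
        "population_mu": prs.population_mu,
        "population_sigma2": prs.population_sigma2,
        "theoretical_auc": theoretical_auc(prs.population_sigma2),
        "group_summaries": groups,
        "median_cutoff": risk_rows,
        "roc": roc_rows,
        "subgroups": subgroups,
        "quartiles": {
            "boundaries": list(quart.boundaries),
            "case_counts": list(quart.case_counts),
            "control_counts": list(quart.control_counts),
            "case_pct": list(quart.case_pct),
            "control_pct": list(quart.control_pct),
            "or_vs_q1": list(quart.or_vs_q1),
            "or_ci_vs_q1": [list(c) for c in quart.or_ci_vs_q1],
        },
    }


def _screening_stage(prs, phenotypes: pd.DataFrame, config: PipelineConfig) -> dict:
    scores = prs.scores
    in_trial = phenotypes["source"].isin(["screening_trial", "control"]).to_numpy()
    trial = phenotypes.loc[in_trial]
    trial_scores = scores[in_trial]
    psa = trial["psa_baseline"].to_numpy(float)
    age = trial["age_baseline"].to_numpy(float)
    status = trial["is_case"].to_numpy(bool)
    if not in_trial.any() or status.all() or not status.any():
        logger.info("stage=screen skipped (no two-class screening cohort)")
        return {"skipped": True}

    table = psa_quartile_table(trial_scores, psa, threshold=config.psa_threshold)
    ok = np.isfinite(psa) & np.isfinite(age)
    models = finrspc_models(status[ok].astype(float), psa[ok], age[ok],
                            trial_scores[ok])
    logger.info(
        "stage=screen n=%d dropped_missing=%d chi2=%.2f",
        int(ok.sum()), int((~ok).sum()), table.chi_square,
    )

    def fit_dict(f, term):
        t = f.term(term)
        return {
            "or": t["or"], "ci": list(t["ci"]), "p": t["p"],
            "auc": f.model_auc, "flagged": f.flagged,
        }

    return {
        "psa_quartile_table": {
            "threshold": table.threshold,
            "quartile_n": list(table.quartile_n),
            "n_negative": list(table.n_negative),
            "n_positive": list(table.n_positive),
            "pct_positive": list(table.pct_positive),
            "chi_square": table.chi_square,
            "pvalue": table.pvalue,
            "n_excluded_missing_psa": table.n_excluded_missing_psa,
        },
        "simple_models": {
            f: fit_dict(models.simple_fits[f], f) for f in models.factors
        },
        "multiple_model": {
            f: fit_dict(models.multiple_fit, f) for f in models.factors
        },
        "cumulative_auc": list(models.cumulative_auc),
    }


def _write_reports(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report["manifest"], fh, indent=2, sort_keys=True)
        fh.write("\n")

    # per-group score summaries
    pd.DataFrame(report["group_summaries"]).T.rename_axis("group").to_csv(
        out / "group_summaries.tsv", sep="\t"
    )
    # risk rows: median-cutoff diagnostics + case-only subgroup analyses
    rows = []
    for name, d in report["median_cutoff"].items():
        rows.append({
            "row": name, "n_above": d["tp"],
            "pct_above": 100.0 * d["tp"] / (d["tp"] + d["fn"]),
            "or": d["odds_ratio"], "or_ci_low": d["or_ci"][0],
            "or_ci_high": d["or_ci"][1], "or_p": d["or_pvalue"],
            "auc": report["roc"].get(name, {}).get("auc"),
        })
    for name, s in report["subgroups"].items():
        rows.append({
            "row": name, "n_above": s["n_above"], "pct_above": s["pct_above"],
            "or": s["odds_ratio"], "or_ci_low": s["or_ci"][0],
            "or_ci_high": s["or_ci"][1], "or_p": s["or_pvalue"],
            "auc": s["auc"],
        })
    pd.DataFrame(rows).to_csv(out / "risk_stratification.tsv", sep="\t", index=False)

    q = report["quartiles"]
    pd.DataFrame({
        "quartile": ["Q1", "Q2", "Q3", "Q4"],
        "cases": q["case_counts"], "case_pct": q["case_pct"],
        "controls": q["control_counts"], "control_pct": q["control_pct"],
        "or_vs_q1": [1.0] + q["or_vs_q1"],
    }).to_csv(out / "quartiles.tsv", sep="\t", index=False)

    scr = report["screening"]
    if not scr.get("skipped"):
        t = scr["psa_quartile_table"]
        pd.DataFrame({
            "quartile": ["Q1", "Q2", "Q3", "Q4"],
            "n": t["quartile_n"], "psa_below": t["n_negative"],
            "psa_at_or_above": t["n_positive"],
            "pct_positive": t["pct_positive"],
        }).to_csv(out / "psa_quartiles.tsv", sep="\t", index=False)
        rows = []
        for f in ("psa", "age", "prs"):
            s, m = scr["simple_models"][f], scr["multiple_model"][f]
            rows.append({
                "factor": f, "simple_or": s["or"], "simple_ci_low": s["ci"][0],
                "simple_ci_high": s["ci"][1], "simple_p": s["p"],
                "simple_auc": s["auc"], "multiple_or": m["or"],
                "multiple_ci_low": m["ci"][0], "multiple_ci_high": m["ci"][1],
                "multiple_p": m["p"],
            })
        df = pd.DataFrame(rows)
        df["cumulative_auc"] = scr["cumulative_auc"]
        df.to_csv(out / "screening_models.tsv", sep="\t", index=False)
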