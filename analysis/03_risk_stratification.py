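#!/usr/bin/env python
"""Risk-stratification evaluation of the PRS on the simulated cohort.

Reproduces the standard evaluation surface: per-group score summaries,
above-control-median diagnostics (sensitivity, specificity, PPV, LR+, OR),
ROC/AUC per case group, case-only subgroup analyses, and the quartile
table with odds ratios against the bottom quartile.  Tables land under
results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd

from finnprs import (
    median_cutoff_summary,
    quartile_stratification,
    roc_auc,
    subgroup_summary,
)
from finnprs.io import read_phenotypes_csv, read_scores


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scores", type=Path, default=Path("results/scores.tsv"))
    ap.add_argument("--phenotypes", type=Path,
                    default=Path("results/data/phenotypes.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    result, _ = read_scores(args.scores)
    ph = read_phenotypes_csv(args.phenotypes)
    scores = result.scores
    is_case = ph["is_case"].to_numpy()
    cases, ctrls = scores[is_case], scores[~is_case]

    rows = []
    for label, sel in [
        ("all cases", is_case),
        ("clinical cases", (ph["source"] == "clinical").to_numpy()),
        ("screening trial cases",
         (ph["source"] == "screening_trial").to_numpy()),
    ]:
        d = median_cutoff_summary(scores[sel], ctrls)
        r = roc_auc(scores[sel], ctrls)
        rows.append({"group": label, "n": int(sel.sum()),
                     "pct_above_median": 100 * d.sensitivity,
                     "or": d.odds_ratio, "or_ci_low": d.or_ci[0],
                     "or_ci_high": d.or_ci[1], "auc": r.auc,
                     "auc_ci_low": r.ci95[0], "auc_ci_high": r.ci95[1]})
    risk = pd.DataFrame(rows)
    risk.to_csv(args.out / "median_cutoff.tsv", sep="\t", index=False)

    d_all = median_cutoff_summary(cases, ctrls)
    print(f"control median cutoff {d_all.cutoff:.3f}: sensitivity "
          f"{d_all.sensitivity:.2f}, specificity {d_all.specificity:.2f}, "
          f"PPV {d_all.ppv:.2f}, LR+ {d_all.lr_positive:.2f}")
    print(f"above-median OR {d_all.odds_ratio:.2f} "
          f"({d_all.or_ci[0]:.2f}-{d_all.or_ci[1]:.2f})")
    r_all = roc_auc(cases, ctrls)
    print(f"AUC {r_all.auc:.3f} ({r_all.ci95[0]:.2f}-{r_all.ci95[1]:.2f})")

    # case-only subgroups, above the same population-control cutoff
    case_ph = ph.loc[is_case]
    sub_rows = []
    for name, flag in [
        ("high PSA at diagnosis (>20)", case_ph["psa_at_diagnosis"] > 20),
        ("Gleason >= 8", case_ph["gleason"].fillna(-1).astype(float) >= 8),
        ("metastatic (M1)", case_ph["m_stage"] == "M1"),
        ("death from disease", case_ph["death_cause"] == "PC"),
    ]:
        f = flag.to_numpy(bool)
        if not f.any() or f.all():
            continue
        s = subgroup_summary(cases, f, d_all.cutoff)
        sub_rows.append({"subgroup": name, "n": s.n_subgroup,
                         "pct_above": 100 * s.frac_above,
                         "or": s.odds_ratio, "or_ci_low": s.or_ci[0],
                         "or_ci_high": s.or_ci[1], "auc": s.auc})
    pd.DataFrame(sub_rows).to_csv(args.out / "subgroups.tsv", sep="\t",
                                  index=False)

    quart = quartile_stratification(cases, ctrls)
    quart.to_frame().to_csv(args.out / "quartiles.tsv", sep="\t", index=False)
    print("case distribution over quartiles:",
          [f"{p:.0f}%" for p in quart.case_pct])
    print("control distribution over quartiles:",
          [f"{p:.0f}%" for p in quart.control_pct])
    print(f"Q4 vs Q1 OR {quart.or_vs_q1[2]:.2f} "
          f"({quart.or_ci_vs_q1[2][0]:.2f}-{quart.or_ci_vs_q1[2][1]:.2f})")
    print(f"wrote median_cutoff.tsv, subgroups.tsv, quartiles.tsv under "
          f"{args.out}")


if __name__ == "__main__":
    main()
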