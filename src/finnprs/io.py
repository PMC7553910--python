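"""Readers and writers for the pipeline's file formats.

Formats: dosage TSV (subjects x SNPs, header = rsids, ``NA`` = missing), a
minimal VCF v4.2 subset (biallelic sites, unphased GT), phenotype CSV, the
panel TSV (see :mod:`finnprs.panel`), and score TSV with a JSON sidecar.
All writers round-trip losslessly through their paired reader.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, PHENOTYPE_COLUMNS
from .exceptions import AlleleMismatchError, FormatError, ValidationError
from .panel import SnpPanel
from .score import PrsResult

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf", "read_genotypes",
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_scores", "read_scores",
]


# ---------------------------------------------------------------- dosage TSV

def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.to_dataframe()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="subject_id", na_values=["NA"])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate subject id {dup!r}")
    try:
        return GenotypeMatrix(
            tuple(str(s) for s in df.index),
            tuple(str(c) for c in df.columns),
            df.to_numpy(dtype=float),
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ----------------------------------------------------------------------- VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##source=finnprs\n"
)


def write_vcf(genotypes: GenotypeMatrix, panel: SnpPanel, path) -> None:
    """Minimal VCF v4.2: REF = other allele, ALT = effect allele, GT only.

    Dosages therefore count ALT alleles; missing dosage becomes ``./.``.
    """
    rec = {r.rsid: r for r in panel.records}
    absent = [s for s in genotypes.snp_ids if s not in rec]
    if absent:
        raise ValidationError(f"write_vcf: SNPs not in panel: {absent[:5]}")
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        for j, rsid in enumerate(genotypes.snp_ids):
            r = rec[rsid]
            col = genotypes.dosages[:, j]
            gts = "\t".join(
                "./." if math.isnan(g) else gt_codes[g] for g in col
            )
            fh.write(
                f"{r.chrom}\t{r.pos}\t{rsid}\t{r.other_allele}\t"
                f"{r.effect_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path, panel: SnpPanel) -> GenotypeMatrix:
    """Read GT dosages from a VCF, oriented to the panel's effect alleles.

    The record's {REF, ALT} pair must equal the panel's {effect, other}
    pair; anything else (including a strand flip) raises
    :class:`AlleleMismatchError` rather than silently flipping.  Half calls
    and ``./.`` become missing.  SNPs in the file but not in the panel are
    ignored.
    """
    from cyvcf2 import VCF  # deferred: import cost only when VCF is used

    rec = {r.rsid: r for r in panel.records}
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid is None or rsid not in rec:
            continue
        if rsid in columns:
            raise FormatError(f"{path}: duplicate record for {rsid}")
        if len(variant.ALT) != 1:
            raise FormatError(f"{path}: {rsid} is not biallelic")
        ref, alt = variant.REF, variant.ALT[0]
        r = rec[rsid]
        if {ref, alt} != {r.effect_allele, r.other_allele}:
            raise AlleleMismatchError(
                f"{rsid}: VCF alleles {ref}/{alt} do not match panel "
                f"{r.effect_allele}/{r.other_allele}"
            )
        effect_is_alt = alt == r.effect_allele
        col = np.full(len(samples), np.nan)
        for i, g in enumerate(variant.genotypes):
            a = [x for x in g[:-1] if x is not None]
            if len(a) != 2 or min(a) < 0:
                continue  # missing or half call
            n_alt = sum(1 for x in a if x == 1)
            col[i] = n_alt if effect_is_alt else 2 - n_alt
        columns[rsid] = col
    vcf.close()
    if not columns:
        raise FormatError(f"{path}: no panel SNPs found in VCF")
    snp_ids = tuple(columns)
    dosages = np.column_stack([columns[s] for s in snp_ids])
    return GenotypeMatrix(samples, snp_ids, dosages)


def read_genotypes(path, fmt: str, panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Dispatch on format: ``dosage_tsv`` or ``vcf`` (needs the panel)."""
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    if fmt == "vcf":
        if panel is None:
            raise ValidationError("read_genotypes: VCF input requires the panel")
        return read_vcf(path, panel)
    raise ValidationError(f"unknown genotype format {fmt!r}")


# ------------------------------------------------------------- phenotype CSV

def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "subject_id": str, "source": str, "t_stage": str,
            "n_stage": str, "m_stage": str, "death_cause": str,
        },
    )
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: phenotype CSV missing columns {missing}")
    df["is_case"] = df["is_case"].astype(bool)
    df["gleason"] = df["gleason"].astype("Int64")
    return df


# ------------------------------------------------------------------- scores

def write_scores(result: PrsResult, panel: SnpPanel, path,
                 missing_mode: str = "mean_impute") -> None:
    """Two-column score TSV plus a JSON sidecar with population parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("subject_id\tprs\n")
        for sid, s in zip(result.subject_ids, result.scores):
            fh.write(f"{sid}\t{s:.15g}\n")
    sidecar = {
        "population_mu": result.population_mu,
        "population_sigma2": result.population_sigma2,
        "panel_sha256": panel.sha256(),
        "n_loci": len(panel),
        "missing_mode": missing_mode,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_scores(path) -> tuple[PrsResult, dict]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     float_precision="round_trip")
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    result = PrsResult(
        tuple(df["subject_id"]),
        df["prs"].to_numpy(dtype=float),
        np.full(len(df), sidecar["n_loci"]),
        sidecar["population_mu"],
        sidecar["population_sigma2"],
    )
    return result, sidecar
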