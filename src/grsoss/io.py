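"""Cohort and genotype file I/O.

Phenotypes travel as CSV (one row per subject, ``subject_id`` the join
key); genotypes either as a dosage CSV (subjects x SNPs, values in
{0, 1, 2}) or as a VCF whose genotype calls are converted to risk-allele
dosages against the SNP panel.  Subject ids, never row order, join the
files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import SNPPanelEntry

__all__ = [
    "read_phenotypes",
    "read_dosage_csv",
    "read_vcf_dosages",
    "read_inputs",
    "write_cohort",
    "write_vcf",
]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: phenotype CSV needs subject_id and label columns")
    if df["label"].isna().any():
        raise ValueError(f"{path}: missing case/control labels")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: labels must be coded 0 (control) / 1 (case)")
    return df


def read_dosage_csv(path) -> pd.DataFrame:
    """Dosage matrix CSV: subject_id column plus one {0,1,2} column per SNP."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: dosage CSV needs a subject_id column")
    snp_cols = [c for c in df.columns if c != "subject_id"]
    for col in snp_cols:
        vals = df[col]
        bad = ~vals.isin([0, 1, 2])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: malformed dosage at row {row}, column {col!r}: "
                f"{vals.iloc[row]!r} (must be 0, 1 or 2)")
        df[col] = vals.astype(int)
    return df


def read_vcf_dosages(path, panel: Sequence[SNPPanelEntry]) -> pd.DataFrame:
    """Convert VCF genotype calls to risk-allele dosages.

    The panel supplies each SNP's risk allele; the dosage is the count of
    that allele among the two called alleles.  The risk allele must match
    the record's REF or ALT, otherwise the SNP is reported as unmatchable.
    Missing calls are rejected (the pipeline has no imputation step).
    """
    from cyvcf2 import VCF  # optional dependency, imported on use

    risk = {e.snp_id: e.risk_allele for e in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        rid = rec.ID
        if rid not in risk:
            continue
        allele = risk[rid]
        alleles = [rec.REF] + list(rec.ALT)
        if allele not in alleles:
            raise ValueError(
                f"risk allele {allele!r} of {rid} matches neither REF ({rec.REF}) "
                f"nor ALT ({','.join(rec.ALT)})")
        target = alleles.index(allele)
        gts = rec.genotypes  # [allele1, allele2, phased]
        dos = np.empty(len(samples), dtype=int)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype call for sample "
                                 f"{samples[i]!r} at {rid}")
            dos[i] = int(a == target) + int(b == target)
        cols[rid] = dos
    missing = sorted(set(risk) - set(cols))
    if missing:
        raise ValueError(f"panel SNPs absent from VCF: {missing}")
    out = pd.DataFrame(cols)
    out.insert(0, "subject_id", samples)
    return out


def read_inputs(geno_path, pheno_path, panel: Sequence[SNPPanelEntry]) -> pd.DataFrame:
    """Load and join phenotypes and genotypes into one cohort table.

    ``geno_path`` may be a dosage CSV or a VCF (suffix .vcf / .vcf.gz).
    Subjects must match one-to-one by id; a mismatch error lists the ids
    private to each file.
    """
    pheno = read_phenotypes(pheno_path)
    name = str(geno_path)
    if name.endswith((".vcf", ".vcf.gz")):
        geno = read_vcf_dosages(geno_path, panel)
    else:
        geno = read_dosage_csv(geno_path)
    ids_p = set(pheno["subject_id"].astype(str))
    ids_g = set(geno["subject_id"].astype(str))
    if ids_p != ids_g:
        raise ValueError(
            "subject ids differ between phenotype and genotype files; "
            f"phenotype-only: {sorted(ids_p - ids_g)[:10]}, "
            f"genotype-only: {sorted(ids_g - ids_p)[:10]}")
    pheno["subject_id"] = pheno["subject_id"].astype(str)
    geno["subject_id"] = geno["subject_id"].astype(str)
    return pheno.merge(geno, on="subject_id", validate="one_to_one")


def write_cohort(cohort: pd.DataFrame, out_prefix,
                 snp_cols: Sequence[str]) -> tuple[Path, Path]:
    """Split a cohort into phenotype and genotype CSVs (``<prefix>_pheno.csv``,
    ``<prefix>_geno.csv``)."""
    out_prefix = Path(out_prefix)
    pheno_path = out_prefix.with_name(out_prefix.name + "_pheno.csv")
    geno_path = out_prefix.with_name(out_prefix.name + "_geno.csv")
    pheno_cols = [c for c in cohort.columns if c not in set(snp_cols)]
    cohort[pheno_cols].to_csv(pheno_path, index=False)
    cohort[["subject_id", *snp_cols]].to_csv(geno_path, index=False)
    return pheno_path, geno_path


def write_vcf(cohort: pd.DataFrame, panel: Sequence[SNPPanelEntry], path) -> None:
    """Minimal diploid VCF export of the panel dosages.

    The risk allele is written as ALT and the dosage as the ALT-allele
    count (REF is a placeholder base differing from the risk allele); this
    round-trips through :func:`read_vcf_dosages`.
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    samples = cohort["subject_id"].astype(str).tolist()
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    gt_by_dosage = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, e in enumerate(panel, start=1):
        ref = "A" if e.risk_allele != "A" else "G"
        gts = [gt_by_dosage[int(d)] for d in cohort[e.snp_id]]
        lines.append(f"1\t{pos}\t{e.snp_id}\t{ref}\t{e.risk_allele}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")
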