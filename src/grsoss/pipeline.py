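"""End-to-end pipeline: simulate/load -> describe -> associate -> score -> ROC.

One :class:`RunConfig` drives a full reproducible run that writes the
report bundle:

* ``table1.tsv``  — group descriptives (unadjusted and adjusted p-values)
* ``table2.tsv``  — per-SNP association results plus the nominal and
  Bonferroni selection flags and the GRS association row
* ``table3.tsv``  — per-biomarker tertile odds ratios and the OSS row
* ``scores.csv``  — per-subject GRS and OSS
* ``roc.tsv``     — AUC and Youden-optimal operating point per risk model
* ``manifest.json`` — seed, package version, config hash

All tables are TSV with a header row; floats are printed at 6 significant
digits.  Two runs with the same config and seed produce byte-identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import (AssociationResult, fit_logistic, select_snps,
                          snp_association)
from .descriptives import describe_table
from .io import read_inputs, write_cohort
from .panel import (SNPPanelEntry, read_panel_csv, reference_oss_cutoffs,
                    reference_panel)
from .roc import DEFAULT_MODELS, ModelSpec, compare_models
from .scoring import GeneticRiskScorer, OxidativeStressScorer
from .simulate import BIOMARKERS, default_config, generate_cohort

logger = logging.getLogger("grsoss")

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` holds {"n_case": ..., "n_control": ...} and the
    cohort is generated from the reference parameters, or ``pheno_path`` /
    ``geno_path`` point at input files.  ``cutoff_mode`` selects
    data-derived OSS tertiles ("data") or the fixed published cutpoints
    ("fixed").
    """

    outdir: str = "grsoss_out"
    seed: int = 0
    simulate: Optional[dict] = None
    pheno_path: Optional[str] = None
    geno_path: Optional[str] = None
    panel_path: Optional[str] = None
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "bmi"])
    biomarkers: list[str] = field(default_factory=lambda: list(BIOMARKERS))
    cutoff_mode: str = "data"
    alpha_nominal: float = 0.05
    models: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    export_pheno_geno: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_nominal < 1.0:
            raise ValueError("alpha_nominal must be in (0, 1)")
        if self.cutoff_mode not in ("data", "fixed"):
            raise ValueError("cutoff_mode must be 'data' or 'fixed'")
        if self.simulate is None and (self.pheno_path is None or self.geno_path is None):
            raise ValueError("need either a simulate block or pheno/geno paths")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _load_panel(config: RunConfig) -> list[SNPPanelEntry]:
    if config.panel_path is not None:
        return read_panel_csv(config.panel_path)
    return reference_panel()


def _get_cohort(config: RunConfig, panel) -> pd.DataFrame:
    if config.simulate is not None:
        sim = default_config(
            n_case=config.simulate.get("n_case"),
            n_control=config.simulate.get("n_control"),
            seed=config.seed)
        logger.info("simulating cohort: %d cases, %d controls, seed %d",
                    sim.n_case, sim.n_control, config.seed)
        return generate_cohort(sim)
    for p in (config.pheno_path, config.geno_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    logger.info("reading cohort from %s + %s", config.pheno_path, config.geno_path)
    return read_inputs(config.geno_path, config.pheno_path, panel)


def _association_table(cohort, panel, covariates, alpha) -> tuple[pd.DataFrame, list[str]]:
    rows, adj_results = [], []
    for e in panel:
        una = snp_association(cohort, e.snp_id)
        adj = snp_association(cohort, e.snp_id, covariates)
        adj_results.append(adj)
        rows.append({
            "snp_id": e.snp_id, "gene": e.gene, "risk_allele": e.risk_allele,
            "raf_case": float(cohort.loc[cohort.label == 1, e.snp_id].mean() / 2),
            "raf_control": float(cohort.loc[cohort.label == 0, e.snp_id].mean() / 2),
            "or_unadjusted": una.or_, "ci_low_unadjusted": una.ci_low,
            "ci_high_unadjusted": una.ci_high, "p_unadjusted": una.p,
            "or_adjusted": adj.or_, "ci_low_adjusted": adj.ci_low,
            "ci_high_adjusted": adj.ci_high, "p_adjusted": adj.p,
        })
    nominal, bonf = select_snps(adj_results, alpha_nominal=alpha, n_tests=len(panel))
    table = pd.DataFrame(rows)
    table["nominal"] = table["snp_id"].isin(nominal).astype(int)
    table["bonferroni"] = table["snp_id"].isin(bonf).astype(int)
    return table, nominal


def _score_row(cohort, col, covariates, name) -> dict:
    res = fit_logistic(cohort["label"].to_numpy(),
                       cohort[[col, *covariates]].astype(float))
    r = res.loc[col]
    return {"component": name, "or": float(np.exp(r["beta"])),
            "ci_low": float(r["ci_low"]), "ci_high": float(r["ci_high"]),
            "p": float(r["p"])}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = _load_panel(config)

    stage = "inputs"
    try:
        cohort = _get_cohort(config, panel)
        snp_cols = [e.snp_id for e in panel if e.snp_id in cohort.columns]
        biomarkers = [b for b in config.biomarkers if b in cohort.columns]
        if config.export_pheno_geno:
            write_cohort(cohort, outdir / "cohort", snp_cols)

        stage = "descriptives"
        logger.info("stage descriptives: %d variables", len(biomarkers) + 3)
        desc_vars = [c for c in ("age", "bmi", *biomarkers) if c in cohort.columns]
        table1 = describe_table(cohort, desc_vars, covariates=config.covariates,
                                log_cols=biomarkers)
        table1.to_csv(outdir / "table1.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)

        stage = "association"
        logger.info("stage association: %d SNPs", len(snp_cols))
        panel_present = [e for e in panel if e.snp_id in cohort.columns]
        table2, nominal = _association_table(
            cohort, panel_present, config.covariates, config.alpha_nominal)

        stage = "scoring"
        grs_snps = nominal if nominal else snp_cols
        if not nominal:
            logger.warning("no SNP passed the nominal filter; "
                           "GRS uses the full panel")
        logger.info("stage scoring: GRS over %d SNPs, OSS over %d biomarkers",
                    len(grs_snps), len(biomarkers))
        grs = GeneticRiskScorer(snp_cols=grs_snps,
                                covariate_cols=config.covariates)
        y = cohort["label"].to_numpy()
        cohort = cohort.copy()
        cohort["grs"] = grs.fit(cohort, y).transform(cohort)[:, 0]
        cutoffs = reference_oss_cutoffs() if config.cutoff_mode == "fixed" else None
        oss = OxidativeStressScorer(biomarker_cols=biomarkers, cutoffs=cutoffs)
        cohort["oss"] = oss.fit(cohort, y).transform(cohort)[:, 0]

        grs_row = _score_row(cohort, "grs", config.covariates, "GRS")
        table2 = pd.concat([table2, pd.DataFrame([{
            "snp_id": "GRS", "gene": "", "risk_allele": "",
            "or_adjusted": grs_row["or"], "ci_low_adjusted": grs_row["ci_low"],
            "ci_high_adjusted": grs_row["ci_high"], "p_adjusted": grs_row["p"],
        }])], ignore_index=True)
        table2.to_csv(outdir / "table2.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)

        tert = oss.tertile_scores(cohort)
        rows = []
        for b in biomarkers:
            tmp = cohort.copy()
            tmp[f"{b}_tertile"] = tert[b].to_numpy()
            rows.append(_score_row(tmp, f"{b}_tertile", config.covariates, b))
        rows.append(_score_row(cohort, "oss", config.covariates, "OSS"))
        pd.DataFrame(rows).to_csv(outdir / "table3.tsv", sep="\t", index=False,
                                  float_format=FLOAT_FMT)

        score_cols = ["subject_id", "label", "bmi", "grs", "oss"]
        cohort[[c for c in score_cols if c in cohort.columns]].to_csv(
            outdir / "scores.csv", index=False, float_format=FLOAT_FMT)

        stage = "roc"
        specs = [m for m in DEFAULT_MODELS if m.model_id in set(config.models)]
        logger.info("stage roc: %d models", len(specs))
        roc_table = compare_models(cohort, specs)
        roc_table.to_csv(outdir / "roc.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": int(len(cohort)),
        "grs_snps": list(grs_snps),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    logger.info("report bundle written to %s", outdir)
    return outdir
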