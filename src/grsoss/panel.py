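"""SNP panel and reference-value handling.

The panel describes the candidate SNPs scored by the pipeline: rsID, nearby
gene, the risk allele, and the risk-allele frequency (RAF) in each outcome
group.  A reference panel for the Korean prediabetes/T2DM case-control study
this package models ships with the package, together with the fixed tertile
cutpoints of the oxidative stress score and the group-level cohort
parameters that the default simulation config is built from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "SNPPanelEntry",
    "load_reference",
    "reference_panel",
    "reference_oss_cutoffs",
    "read_panel_csv",
    "write_panel_csv",
]


@dataclass
class SNPPanelEntry:
    """One SNP of the candidate panel.

    Parameters
    ----------
    snp_id : str
        rsID, non-empty.
    gene : str
        Nearby gene symbol (annotation only).
    risk_allele : str
        The allele counted by the dosage coding.
    raf_case, raf_control : float
        Risk-allele frequency per outcome group, in [0, 1].
    reference : dict
        Optional published association results (p-values, odds ratios)
        carried along for reporting; never used in computation.
    """

    snp_id: str
    gene: str = ""
    risk_allele: str = ""
    raf_case: float = float("nan")
    raf_control: float = float("nan")
    reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be a non-empty rsID string")
        for name in ("raf_case", "raf_control"):
            raf = getattr(self, name)
            if raf == raf and not 0.0 <= raf <= 1.0:  # NaN allowed (unknown)
                raise ValueError(f"{name}={raf} outside [0, 1] for {self.snp_id}")


def load_reference() -> dict:
    """Return the shipped reference-value dictionary (parsed JSON)."""
    text = resources.files("grsoss.data").joinpath("reference_panel.json").read_text()
    return json.loads(text)


def reference_panel() -> list[SNPPanelEntry]:
    """The nine-SNP reference panel with published group RAFs."""
    ref = load_reference()
    entries = []
    for row in ref["panel"]:
        extra = {k: v for k, v in row.items()
                 if k not in ("snp_id", "gene", "risk_allele", "raf_case", "raf_control")}
        entries.append(SNPPanelEntry(
            snp_id=row["snp_id"], gene=row["gene"], risk_allele=row["risk_allele"],
            raf_case=row["raf_case"], raf_control=row["raf_control"], reference=extra))
    return entries


def reference_oss_cutoffs() -> dict[str, tuple[float, float]]:
    """Fixed (c1, c2) tertile cutpoints of the oxidative-stress biomarkers."""
    ref = load_reference()
    return {name: (d["c1"], d["c2"]) for name, d in ref["oss_cutoffs"].items()}


def read_panel_csv(path) -> list[SNPPanelEntry]:
    """Read a panel CSV with columns snp_id, gene, risk_allele, raf_case, raf_control."""
    df = pd.read_csv(path)
    required = {"snp_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing required columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(SNPPanelEntry(
            snp_id=str(row["snp_id"]),
            gene=str(row.get("gene", "") or ""),
            risk_allele=str(row.get("risk_allele", "") or ""),
            raf_case=float(row.get("raf_case", float("nan"))),
            raf_control=float(row.get("raf_control", float("nan"))),
        ))
    return entries


def write_panel_csv(panel: list[SNPPanelEntry], path) -> None:
    pd.DataFrame([
        {"snp_id": e.snp_id, "gene": e.gene, "risk_allele": e.risk_allele,
         "raf_case": e.raf_case, "raf_control": e.raf_control}
        for e in panel
    ]).to_csv(path, index=False)
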