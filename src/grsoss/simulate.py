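"""Synthetic case-control cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: genotypes drawn under Hardy-Weinberg equilibrium within each
outcome group at the group's risk-allele frequency, log-normal biomarkers
matched (by method of moments) to target arithmetic group means and SEs,
and normal/Bernoulli covariates per group.  The defaults replicate the
published group parameters of the Korean prediabetes/T2DM cohort (549
cases, 1036 controls).

Reproducibility contract: a :class:`SimulationConfig` carries one master
seed; :func:`generate_cohort` spawns independent named substreams for
genotypes, biomarkers and covariates so adding one sampler never perturbs
the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SNPPanelEntry, load_reference, reference_panel

__all__ = [
    "BiomarkerSpec",
    "NormalCovariateSpec",
    "SimulationConfig",
    "default_config",
    "simulate_genotypes",
    "simulate_biomarkers",
    "generate_cohort",
]

BIOMARKERS = ("mda", "ox_ldl", "epi_pgf2a")


@dataclass
class BiomarkerSpec:
    """Per-group arithmetic mean and standard error of one biomarker."""

    mean_control: float
    se_control: float
    mean_case: float
    se_case: float

    def __post_init__(self) -> None:
        if self.mean_control <= 0 or self.mean_case <= 0:
            raise ValueError("biomarker group means must be strictly positive")
        # se == 0 is the degenerate constant-value case, allowed for testing
        if self.se_control < 0 or self.se_case < 0:
            raise ValueError("biomarker group SEs must be non-negative")


@dataclass
class NormalCovariateSpec:
    """Per-group mean and SE of a normal covariate (age, BMI)."""

    mean_control: float
    se_control: float
    mean_case: float
    se_case: float

    def __post_init__(self) -> None:
        if self.se_control <= 0 or self.se_case <= 0:
            raise ValueError("covariate group SEs must be strictly positive")


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    SEs are the printed per-group standard errors of the mean; the sampler
    reconstructs the group SD as ``SE * sqrt(n_group)``, so a config whose
    group sizes match the source table reproduces the source SDs exactly.
    """

    n_case: int
    n_control: int
    panel: list[SNPPanelEntry]
    biomarker_specs: dict[str, BiomarkerSpec]
    covariate_specs: dict[str, NormalCovariateSpec]
    prop_male_control: float = 0.5
    prop_male_case: float = 0.5
    correlation: Optional[np.ndarray] = None  # biomarker rank-correlation matrix
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must each be >= 1")
        for p in (self.prop_male_control, self.prop_male_case):
            if not 0.0 <= p <= 1.0:
                raise ValueError("sex proportions must be in [0, 1]")
        for e in self.panel:
            for raf in (e.raf_case, e.raf_control):
                if not 0.0 <= raf <= 1.0:
                    raise ValueError(f"RAF outside [0, 1] for {e.snp_id}")
        if self.correlation is not None:
            self.correlation = _validate_correlation(
                np.asarray(self.correlation, dtype=float), len(self.biomarker_specs))


def _validate_correlation(corr: np.ndarray, k: int) -> np.ndarray:
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}, got {corr.shape}")
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError(f"correlation matrix not positive semi-definite "
                         f"(min eigenvalue {eigmin:.3g})")
    return corr


def default_config(n_case: Optional[int] = None, n_control: Optional[int] = None,
                   seed: int = 0,
                   correlation: Optional[np.ndarray] = None) -> SimulationConfig:
    """Config calibrated to the published group-level cohort parameters."""
    ref = load_reference()
    bm = {name: BiomarkerSpec(**spec) for name, spec in ref["biomarker_specs"].items()}
    cov = {name: NormalCovariateSpec(**spec)
           for name, spec in ref["covariate_specs"].items() if name != "sex"}
    sex = ref["covariate_specs"]["sex"]
    return SimulationConfig(
        n_case=n_case if n_case is not None else ref["n_case"],
        n_control=n_control if n_control is not None else ref["n_control"],
        panel=reference_panel(),
        biomarker_specs=bm,
        covariate_specs=cov,
        prop_male_control=sex["prop_male_control"],
        prop_male_case=sex["prop_male_case"],
        correlation=correlation,
        seed=seed,
    )


def simulate_genotypes(panel: Sequence[SNPPanelEntry], n_case: int, n_control: int,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw risk-allele dosages under within-group Hardy-Weinberg equilibrium.

    Each subject's dosage at a SNP is Binomial(2, group RAF).  Returns a
    (n_case + n_control) x n_snp dosage DataFrame (columns = rsIDs; cases
    first) and the matching 0/1 label vector.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("both groups must have at least one subject")
    for e in panel:
        for raf in (e.raf_case, e.raf_control):
            if not 0.0 <= raf <= 1.0:
                raise ValueError(f"RAF outside [0, 1] for {e.snp_id}")
    labels = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    cols = {}
    for e in panel:
        case_d = rng.binomial(2, e.raf_case, size=n_case)
        ctrl_d = rng.binomial(2, e.raf_control, size=n_control)
        cols[e.snp_id] = np.concatenate([case_d, ctrl_d])
    return pd.DataFrame(cols), labels


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # method of moments on the arithmetic scale; sd == 0 -> degenerate constant
    if sd == 0.0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_biomarkers(specs: dict[str, BiomarkerSpec], labels: np.ndarray,
                        n_case: int, n_control: int,
                        rng: np.random.Generator,
                        correlation: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Draw per-subject biomarker values, log-normal within each group.

    The log-normal (mu, sigma) are solved by method of moments from the
    target arithmetic mean and SD, with SD reconstructed as SE * sqrt(n) of
    the group.  An optional Gaussian copula imposes a rank-correlation
    structure across biomarkers; the default is within-group independence.
    """
    labels = np.asarray(labels)
    names = list(specs)
    k = len(names)
    if correlation is not None:
        correlation = _validate_correlation(np.asarray(correlation, float), k)
    out = np.empty((labels.size, k))
    for is_case, n_group in ((True, n_case), (False, n_control)):
        mask = labels == (1 if is_case else 0)
        m = int(mask.sum())
        # copula: correlated standard normals -> uniform ranks
        if correlation is not None:
            chol = np.linalg.cholesky(correlation + 1e-12 * np.eye(k))
            z = rng.standard_normal((m, k)) @ chol.T
        else:
            z = rng.standard_normal((m, k))
        u = stats.norm.cdf(z)
        for j, name in enumerate(names):
            s = specs[name]
            mean = s.mean_case if is_case else s.mean_control
            se = s.se_case if is_case else s.se_control
            mu, sigma = _lognormal_params(mean, se * np.sqrt(n_group))
            if sigma == 0.0:
                out[mask, j] = mean
            else:
                out[mask, j] = np.exp(mu + sigma * stats.norm.ppf(u[:, j]))
    return pd.DataFrame(out, columns=names)


def _simulate_covariates(config: SimulationConfig, labels: np.ndarray,
                         rng: np.random.Generator) -> pd.DataFrame:
    n = labels.size
    cols: dict[str, np.ndarray] = {}
    for name, spec in config.covariate_specs.items():
        vals = np.empty(n)
        for is_case, n_group in ((True, config.n_case), (False, config.n_control)):
            mask = labels == (1 if is_case else 0)
            mean = spec.mean_case if is_case else spec.mean_control
            se = spec.se_case if is_case else spec.se_control
            sd = se * np.sqrt(n_group)
            vals[mask] = rng.normal(mean, sd, size=int(mask.sum()))
        cols[name] = vals
    sex = np.empty(n, dtype=int)
    for is_case, prop in ((True, config.prop_male_case), (False, config.prop_male_control)):
        mask = labels == (1 if is_case else 0)
        sex[mask] = rng.binomial(1, prop, size=int(mask.sum()))
    cols["sex"] = sex
    return pd.DataFrame(cols)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a full synthetic cohort table.

    Columns: subject_id, label (1 = prediabetes/T2DM case), sex
    (0 = female, 1 = male), the configured covariates, the biomarkers, and
    one dosage column per panel SNP.  Identical config and seed give a
    bitwise-identical table.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(0,))
    streams = {name: np.random.default_rng(child)
               for name, child in zip(("genotypes", "biomarkers", "covariates"),
                                      ss.spawn(3))}
    dosages, labels = simulate_genotypes(
        config.panel, config.n_case, config.n_control, streams["genotypes"])
    biomarkers = simulate_biomarkers(
        config.biomarker_specs, labels, config.n_case, config.n_control,
        streams["biomarkers"], config.correlation)
    covariates = _simulate_covariates(config, labels, streams["covariates"])
    n = labels.size
    width = len(str(n))
    cohort = pd.concat(
        [pd.DataFrame({"subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
                       "label": labels}),
         covariates, biomarkers, dosages],
        axis=1)
    return cohort
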