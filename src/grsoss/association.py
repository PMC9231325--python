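"""Per-SNP association testing and multiple-testing filters.

Additive (per-allele) logistic regression of case status on risk-allele
dosage, unadjusted or adjusted for covariates; allele-table odds ratios
reconstructed from group risk-allele frequencies with a Woolf confidence
interval and a Pearson chi-square test; and the nominal / Bonferroni SNP
selection used to define the genetic risk score panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "AssociationResult",
    "SeparationError",
    "fit_logistic",
    "snp_association",
    "allele_or",
    "select_snps",
    "bonferroni_threshold",
]

Z95 = stats.norm.ppf(0.975)

# |log-odds| beyond this while the likelihood keeps improving is read as
# (quasi-)complete separation rather than a real effect
SEPARATION_BETA = 15.0


class SeparationError(ValueError):
    """Raised when the outcome is (quasi-)completely separated by a predictor."""


@dataclass
class AssociationResult:
    """Per-predictor logistic association estimate."""

    snp_id: str
    beta: float            # log-odds per risk allele
    se: float
    or_: float             # exp(beta)
    ci_low: float          # 95% Wald bounds on the OR scale
    ci_high: float
    p: float               # Wald p-value
    adjusted: bool = False


def fit_logistic(outcome, predictors, include_intercept: bool = True,
                 lrt: bool = False) -> pd.DataFrame:
    """Maximum-likelihood logistic regression via IRLS.

    Parameters
    ----------
    outcome : binary vector
    predictors : 2-D array or DataFrame (columns are predictors)
    include_intercept : prepend a constant column.
    lrt : also report likelihood-ratio p-values (column ``p_lrt``), one
        single-term deletion per predictor.

    Returns
    -------
    DataFrame indexed by coefficient name with columns beta, se, p,
    ci_low, ci_high (CI on the odds-ratio scale, exp(beta +/- 1.96 se)).

    Raises
    ------
    ValueError
        One-class outcome or rank-deficient design.
    SeparationError
        Complete or quasi-complete separation (any |beta| > 15 while the
        fit still improves, or an exactly separating predictor).
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    if isinstance(predictors, pd.DataFrame):
        X = predictors.copy()
    else:
        arr = np.atleast_2d(np.asarray(predictors, dtype=float))
        if arr.shape[0] == 1 and y.size != 1:
            arr = arr.T
        X = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    if include_intercept:
        X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(constant or collinear predictor column)")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = model.fit(maxiter=100, tol=1e-8)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation detected in logistic fit: {exc}") from exc
    params = fit.params
    # the intercept is exempt: it legitimately grows large with uncentred
    # covariates (e.g. BMI on its natural scale)
    slopes = params.drop(index="const", errors="ignore")
    if np.any(np.abs(slopes.to_numpy()) > SEPARATION_BETA):
        raise SeparationError(
            "separation detected in logistic fit: "
            f"|beta| > {SEPARATION_BETA} for {slopes.abs().idxmax()}")
    se = fit.bse
    out = pd.DataFrame({
        "beta": params, "se": se,
        "p": 2 * stats.norm.sf(np.abs(params / se)),
        "ci_low": np.exp(params - Z95 * se),
        "ci_high": np.exp(params + Z95 * se),
    })
    if lrt:
        p_lrt = []
        for col in X.columns:
            reduced = sm.GLM(y, X.drop(columns=col),
                             family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
            lr = 2 * (fit.llf - reduced.llf)
            p_lrt.append(stats.chi2.sf(max(lr, 0.0), df=1))
        out["p_lrt"] = p_lrt
    return out


def snp_association(cohort: pd.DataFrame, snp_id: str,
                    covariates: Sequence[str] = ()) -> AssociationResult:
    """Additive per-allele logistic association of one SNP with case status."""
    if snp_id not in cohort.columns:
        raise KeyError(f"dosage column {snp_id!r} not found in cohort")
    X = cohort[[snp_id, *covariates]].astype(float)
    res = fit_logistic(cohort["label"].to_numpy(), X)
    row = res.loc[snp_id]
    return AssociationResult(
        snp_id=snp_id, beta=float(row["beta"]), se=float(row["se"]),
        or_=float(np.exp(row["beta"])), ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]), p=float(row["p"]),
        adjusted=bool(covariates))


def allele_or(raf_case: float, raf_control: float, n_case: int,
              n_control: int) -> tuple[float, tuple[float, float], float]:
    """Allele-table odds ratio from group risk-allele frequencies.

    Reconstructs the 2x2 allele-count table (2n chromosomes per group,
    counts rounded to nearest integer) and returns the cross-product OR,
    the Woolf (log-scale) 95% CI, and the Pearson chi-square p-value.
    """
    for raf in (raf_case, raf_control):
        if not 0.0 < raf < 1.0:
            raise ValueError("allele frequencies must lie strictly in (0, 1) "
                             "for a finite log odds ratio")
    a = round(2 * n_case * raf_case)        # risk alleles in cases
    b = 2 * n_case - a
    c = round(2 * n_control * raf_control)  # risk alleles in controls
    d = 2 * n_control - c
    if min(a, b, c, d) == 0:
        raise ValueError("degenerate allele table after rounding (zero cell)")
    or_ = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(or_ * np.exp(-Z95 * se_log)), float(or_ * np.exp(Z95 * se_log)))
    _, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(or_), ci, float(p)


def select_snps(results, alpha_nominal: float = 0.05,
                n_tests: Optional[int] = None) -> tuple[list[str], list[str]]:
    """Nominal and Bonferroni SNP filters.

    ``results`` is a list of :class:`AssociationResult` or of (snp_id, p)
    pairs.  The Bonferroni divisor defaults to the full panel size (the
    number of results), not the size of the selected set.
    """
    pairs = [(r.snp_id, r.p) if isinstance(r, AssociationResult) else tuple(r)
             for r in results]
    if n_tests is None:
        n_tests = len(pairs)
    if pairs and n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    nominal = [s for s, p in pairs if p < alpha_nominal]
    bonf = [s for s, p in pairs if p < alpha_nominal / max(n_tests, 1)]
    return nominal, bonf


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 9) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
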