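"""Two-group descriptive comparisons.

Reproduces the standard baseline-characteristics analysis surface: per-group
mean +/- SE on the original measurement scale, an unadjusted two-sided
independent t-test (optionally on log-transformed values for skewed
variables), and a covariate-adjusted comparison via an ANCOVA-style linear
model of the (optionally logged) response on the group indicator plus
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["GroupComparison", "group_compare", "adjusted_compare", "describe_table"]


@dataclass
class GroupComparison:
    variable: str
    mean_control: float
    se_control: float
    mean_case: float
    se_case: float
    p_unadjusted: float
    p_adjusted: Optional[float] = None
    log_transformed: bool = False


def _split(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    case, ctrl = values[labels == 1], values[labels == 0]
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    return case, ctrl


def group_compare(values, labels, log_transform: bool = False,
                  variable: str = "", welch: bool = False) -> GroupComparison:
    """Unadjusted two-group comparison.

    Reports per-group mean +/- SE on the original scale; the p-value comes
    from a two-sided independent t-test on the (optionally log-transformed)
    values.  The classical pooled-variance t-test is the default; ``welch``
    switches to the unequal-variance form.
    """
    case, ctrl = _split(values, labels)
    tvals_case, tvals_ctrl = case, ctrl
    if log_transform:
        if np.any(case <= 0) or np.any(ctrl <= 0):
            raise ValueError("log_transform requires strictly positive values")
        tvals_case, tvals_ctrl = np.log(case), np.log(ctrl)
    _, p = stats.ttest_ind(tvals_case, tvals_ctrl, equal_var=not welch)
    return GroupComparison(
        variable=variable,
        mean_control=float(ctrl.mean()), se_control=float(stats.sem(ctrl)),
        mean_case=float(case.mean()), se_case=float(stats.sem(case)),
        p_unadjusted=float(p), log_transformed=log_transform)


def adjusted_compare(values, labels, covariates=None,
                     log_transform: bool = False) -> float:
    """Covariate-adjusted group comparison (ANCOVA-equivalent).

    Fits OLS of the (optionally logged) response on intercept + group
    indicator + covariates and returns the two-sided p-value of the group
    coefficient.  With no covariates this reduces exactly to the pooled
    t-test (F = t^2 identity).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if log_transform:
        if np.any(values <= 0):
            raise ValueError("log_transform requires strictly positive values")
        values = np.log(values)
    X = pd.DataFrame({"group": labels})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        bad = []
        cols = X.columns.tolist()
        for j in range(X.shape[1]):
            keep = [c for i, c in enumerate(cols) if i != j]
            if np.linalg.matrix_rank(X[keep].to_numpy()) == rank:
                bad.append(cols[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(values, X).fit()
    return float(fit.pvalues["group"])


def describe_table(cohort: pd.DataFrame, variables: Sequence[str],
                   covariates: Sequence[str] = ("age", "sex", "bmi"),
                   log_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Baseline-characteristics table: one row per variable.

    Each row carries group means +/- SE, the unadjusted t-test p and the
    covariate-adjusted p.  A variable that is itself an adjustment covariate
    gets no adjusted p (reported as NaN).
    """
    rows = []
    labels = cohort["label"].to_numpy()
    for var in variables:
        log_t = var in log_cols
        gc = group_compare(cohort[var], labels, log_transform=log_t, variable=var)
        if var in covariates:
            p_adj = np.nan
        else:
            cov = cohort[list(covariates)]
            p_adj = adjusted_compare(cohort[var], labels, cov, log_transform=log_t)
        gc.p_adjusted = p_adj
        rows.append(gc)
    return pd.DataFrame([vars(r) for r in rows])
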