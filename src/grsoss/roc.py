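"""ROC analysis, Youden-optimal cutoffs, and risk-model comparison.

The ROC curve is built on the distinct observed score values (ties grouped
into a single vertex, infinite sentinels at both ends) and its AUC is the
trapezoidal area — identical, by construction, to the Mann-Whitney rank
statistic ``P(case > control) + 0.5 P(tie)`` which :func:`auc_rank`
computes independently as a cross-check.

The model-comparison surface mirrors a six-model screen over BMI, the
oxidative stress score and the genetic risk score: single-feature models
are ranked by the raw feature, multi-feature models by the in-sample
predicted probability of a logistic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn import metrics as skm

from .association import fit_logistic

__all__ = [
    "ROCCurve",
    "CutoffResult",
    "ModelSpec",
    "DEFAULT_MODELS",
    "roc_curve",
    "auc_rank",
    "youden_cutoff",
    "optimal_cutoff",
    "fit_model_score",
    "compare_models",
    "stepwise_select",
]


@dataclass
class ROCCurve:
    """Threshold-ordered ROC curve.

    ``thresholds`` is descending and starts with +inf (classify nothing
    positive); each subsequent entry is a distinct observed score value and
    the classification rule at threshold t is "positive iff score >= t".
    Sensitivity is non-decreasing down the list, specificity non-increasing;
    the curve runs from (sens 0, spec 1) to (sens 1, spec 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class CutoffResult:
    """An operating point selected on a ROC curve."""

    variable: str
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class ModelSpec:
    """One candidate risk model: an id and the features it uses."""

    model_id: int
    features: list[str]


DEFAULT_MODELS = [
    ModelSpec(1, ["bmi"]),
    ModelSpec(2, ["oss"]),
    ModelSpec(3, ["grs"]),
    ModelSpec(4, ["bmi", "oss"]),
    ModelSpec(5, ["oss", "grs"]),
    ModelSpec(6, ["bmi", "oss", "grs"]),
]


def _check_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    classes = set(np.unique(y))
    if classes != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return s, y


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve over the distinct score values, AUC by the trapezoidal rule."""
    s, y = _check_scores(scores, labels)
    fpr, tpr, thr = skm.roc_curve(y, s, drop_intermediate=False)
    sens, spec = tpr, 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr.astype(float), sensitivity=sens,
                    specificity=spec, auc=auc)


def auc_rank(scores, labels) -> float:
    """Mann-Whitney AUC: mean over case-control pairs of wins + half-ties.

    Computed from midranks, independent of the trapezoidal route.
    """
    s, y = _check_scores(scores, labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    ranks = stats.rankdata(s)
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden_cutoff(curve: ROCCurve, scores=None, labels=None,
                  variable: str = "", criterion: str = "youden") -> CutoffResult:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    The reported cutoff is the midpoint between the selected threshold and
    the next lower distinct score value, so "score > cutoff" reproduces the
    selected vertex exactly; ties in J break toward the lowest cutoff.
    ``criterion="closest01"`` minimizes the Euclidean distance to the
    (sens 1, spec 1) corner instead.
    """
    thr = np.asarray(curve.thresholds, dtype=float)
    sens = np.asarray(curve.sensitivity, dtype=float)
    spec = np.asarray(curve.specificity, dtype=float)
    j = sens + spec - 1.0
    if criterion == "youden":
        objective = j
    elif criterion == "closest01":
        objective = -np.hypot(1.0 - sens, 1.0 - spec)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    # scan from the low-cutoff end (end of the descending threshold list) so
    # argmax ties resolve toward the lowest cutoff
    order = np.arange(thr.size)[::-1]
    best = order[np.argmax(objective[order])]
    finite = thr[np.isfinite(thr)]
    if best == 0:                       # the +inf sentinel: nothing positive
        cutoff = np.inf
    else:
        t = thr[best]
        lower = finite[finite < t]
        cutoff = float((t + lower.max()) / 2) if lower.size else -np.inf
    return CutoffResult(variable=variable, cutoff=float(cutoff),
                        sensitivity=float(sens[best]),
                        specificity=float(spec[best]),
                        youden_j=float(j[best]))


def optimal_cutoff(scores, labels, variable: str = "",
                   criterion: str = "youden") -> CutoffResult:
    """Convenience: ROC curve + Youden scan in one call."""
    return youden_cutoff(roc_curve(scores, labels), variable=variable,
                         criterion=criterion)


def fit_model_score(cohort: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Per-subject risk score of one candidate model.

    Single-feature models return the raw feature (ROC analysis is invariant
    to monotone rescaling, so no fit is needed); multi-feature models return
    the in-sample predicted probability of a logistic fit of the label on
    the features.
    """
    missing = [f for f in spec.features if f not in cohort.columns]
    if missing:
        raise KeyError(f"model {spec.model_id} features not in cohort: {missing}")
    if len(spec.features) == 1:
        col = cohort[spec.features[0]].to_numpy(dtype=float)
        if np.all(col == col[0]):
            raise ValueError(f"model {spec.model_id}: constant feature "
                             f"{spec.features[0]!r}")
        return col
    y = cohort["label"].to_numpy()
    X = cohort[spec.features].astype(float)
    res = fit_logistic(y, X)
    lin = sm.add_constant(X, has_constant="add").to_numpy() @ res["beta"].to_numpy()
    return 1.0 / (1.0 + np.exp(-lin))


def compare_models(cohort: pd.DataFrame,
                   specs: Sequence[ModelSpec] = DEFAULT_MODELS) -> pd.DataFrame:
    """AUC and Youden-optimal operating point for each candidate model."""
    if not specs:
        raise ValueError("need at least one model spec")
    rows = []
    y = cohort["label"].to_numpy()
    for spec in specs:
        s = fit_model_score(cohort, spec)
        curve = roc_curve(s, y)
        cut = youden_cutoff(curve, variable="+".join(spec.features))
        rows.append({
            "model_id": spec.model_id,
            "features": "+".join(spec.features),
            "auc": curve.auc,
            "cutoff": cut.cutoff,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
        })
    return pd.DataFrame(rows)


def stepwise_select(cohort: pd.DataFrame, candidates: Sequence[str],
                    excluded: Sequence[str] = (),
                    p_enter: float = 0.05, p_remove: float = 0.10,
                    max_steps: int = 100) -> list[str]:
    """Forward stepwise logistic selection with backward pruning.

    A candidate enters when its Wald p in the current model is the smallest
    and < ``p_enter``; after each entry, any retained term whose p rises
    above ``p_remove`` is dropped.  Stops at a fixed point.
    """
    pool = [c for c in candidates if c not in set(excluded)]
    y = cohort["label"].to_numpy()
    selected: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward step
        best_p, best_c = None, None
        for c in pool:
            if c in selected:
                continue
            res = fit_logistic(y, cohort[[*selected, c]].astype(float))
            p = float(res.loc[c, "p"])
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            selected.append(best_c)
            changed = True
        # backward step
        while len(selected) > 0:
            res = fit_logistic(y, cohort[selected].astype(float))
            pvals = res.loc[selected, "p"]
            worst = pvals.idxmax()
            if float(pvals[worst]) > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return selected
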