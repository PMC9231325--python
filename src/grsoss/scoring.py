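"""Weighted genetic risk score (GRS) and oxidative stress score (OSS).

Both scores share one arithmetic: a per-subject weighted sum
``score = sum_k beta_k * value_k`` where the weights are log-odds
coefficients from logistic regression and the component values are small
integer codes in {0, 1, 2}.

* GRS: value_k is the risk-allele dosage of SNP k; each weight comes from a
  per-SNP covariate-adjusted additive logistic fit.
* OSS: value_k is the tertile score (T1 = 0, T2 = 1, T3 = 2) of an
  oxidative-stress biomarker (MDA, ox-LDL, 8-epi-PGF2a); the three weights
  come from one joint logistic fit on the tertile scores.

Tertile boundaries use upper-inclusive intervals (-inf, c1], (c1, c2],
(c2, inf); cutpoints are either derived from the data (1/3 and 2/3 sample
quantiles, linear interpolation) or fixed published values.

The two scorers are scikit-learn compatible transformers
(:class:`GeneticRiskScorer`, :class:`OxidativeStressScorer`): ``fit`` learns
the weights (and, for the OSS, the cutpoints) from a labelled cohort, and
``transform`` appends nothing — it returns the per-subject score column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .association import fit_logistic

__all__ = [
    "TertileCutoffs",
    "ScoreWeights",
    "tertile_cutoffs",
    "assign_tertile",
    "fit_component_weights",
    "weighted_score",
    "GeneticRiskScorer",
    "OxidativeStressScorer",
]


@dataclass
class TertileCutoffs:
    """The two cutpoints splitting a biomarker into tertile categories."""

    biomarker: str
    c1: float
    c2: float
    source: str = "data_derived"  # or "fixed"

    def __post_init__(self) -> None:
        if not self.c1 < self.c2:
            raise ValueError(f"need c1 < c2, got ({self.c1}, {self.c2})")


@dataclass
class ScoreWeights:
    """Named component -> log-odds weight mapping for one score."""

    weights: dict[str, float]
    component_kind: str  # "allele_dosage" or "tertile_score"

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("all weights must be finite")


def tertile_cutoffs(values, biomarker: str = "",
                    source: str = "data_derived") -> TertileCutoffs:
    """Sample 1/3 and 2/3 quantiles by linear interpolation (h = (n-1)p + 1)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least 3 finite values for tertiles")
    if np.all(v == v[0]):
        raise ValueError("degenerate distribution: all values equal")
    c1, c2 = np.quantile(v, [1 / 3, 2 / 3], method="linear")
    if c1 == c2:
        raise ValueError("degenerate distribution: tertile cutpoints coincide")
    return TertileCutoffs(biomarker=biomarker, c1=float(c1), c2=float(c2), source=source)


def assign_tertile(value, cutoffs: TertileCutoffs):
    """Tertile score in {0, 1, 2}; boundaries are upper-inclusive.

    value <= c1 -> 0;  c1 < value <= c2 -> 1;  value > c2 -> 2.
    Accepts a scalar or a vector.
    """
    v = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(v)):
        raise ValueError("tertile assignment requires finite values (no NaN)")
    score = np.where(v <= cutoffs.c1, 0, np.where(v <= cutoffs.c2, 1, 2))
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(score)
    return score.astype(int)


def fit_component_weights(cohort: pd.DataFrame, components: Sequence[str],
                          component_kind: str,
                          covariates: Sequence[str] = ()) -> ScoreWeights:
    """Estimate the log-odds weight of each score component.

    ``allele_dosage``: one covariate-adjusted logistic fit per SNP; the
    weight is that SNP's dosage coefficient.  ``tertile_score``: one joint
    logistic fit with all components (plus covariates) as predictors.
    """
    if component_kind not in ("allele_dosage", "tertile_score"):
        raise ValueError(f"unknown component_kind {component_kind!r}")
    missing = [c for c in components if c not in cohort.columns]
    if missing:
        raise KeyError(f"components not in cohort: {missing}")
    y = cohort["label"].to_numpy()
    weights: dict[str, float] = {}
    if component_kind == "allele_dosage":
        for comp in components:
            X = cohort[[comp, *covariates]].astype(float)
            res = fit_logistic(y, X)
            weights[comp] = float(res.loc[comp, "beta"])
    else:
        X = cohort[[*components, *covariates]].astype(float)
        res = fit_logistic(y, X)
        for comp in components:
            weights[comp] = float(res.loc[comp, "beta"])
    return ScoreWeights(weights=weights, component_kind=component_kind)


def weighted_score(component_values, weights: ScoreWeights) -> np.ndarray | float:
    """score = sum_k beta_k * value_k over the weighted components.

    ``component_values`` is a mapping name -> value (scalar score) or a
    DataFrame (per-subject score vector).
    """
    names = list(weights.weights)
    if isinstance(component_values, pd.DataFrame):
        missing = [n for n in names if n not in component_values.columns]
        if missing:
            raise KeyError(f"missing score components: {missing}")
        mat = component_values[names].to_numpy(dtype=float)
        beta = np.array([weights.weights[n] for n in names])
        return mat @ beta
    missing = [n for n in names if n not in component_values]
    if missing:
        raise KeyError(f"missing score components: {missing}")
    return float(sum(weights.weights[n] * component_values[n] for n in names))


class GeneticRiskScorer(BaseEstimator, TransformerMixin):
    """Beta-weighted genetic risk score as a scikit-learn transformer.

    ``fit(X, y)`` estimates one log-odds weight per SNP from per-SNP
    additive logistic fits of the outcome on dosage (adjusted for
    ``covariate_cols`` when present in X); ``transform(X)`` returns the
    per-subject weighted dosage sum as an (n, 1) array.

    Parameters
    ----------
    snp_cols : list of dosage column names; None = every column of X not
        named in covariate_cols.
    covariate_cols : adjustment covariates used during fitting only.
    joint : fit one joint logistic model over all SNPs instead of per-SNP
        fits.

    Attributes
    ----------
    weights_ : ScoreWeights
    snp_cols_ : list of str
    """

    def __init__(self, snp_cols: Optional[Sequence[str]] = None,
                 covariate_cols: Sequence[str] = ("age", "sex", "bmi"),
                 joint: bool = False):
        self.snp_cols = snp_cols
        self.covariate_cols = covariate_cols
        self.joint = joint

    def fit(self, X: pd.DataFrame, y):
        X = self._check_frame(X)
        cols = (list(self.snp_cols) if self.snp_cols is not None
                else [c for c in X.columns if c not in set(self.covariate_cols)])
        if not cols:
            raise ValueError("no SNP dosage columns to score")
        covs = [c for c in self.covariate_cols if c in X.columns]
        cohort = X.copy()
        cohort["label"] = np.asarray(y)
        if self.joint:
            res = fit_logistic(cohort["label"].to_numpy(),
                               cohort[[*cols, *covs]].astype(float))
            self.weights_ = ScoreWeights(
                {c: float(res.loc[c, "beta"]) for c in cols}, "allele_dosage")
        else:
            self.weights_ = fit_component_weights(cohort, cols, "allele_dosage", covs)
        self.snp_cols_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = self._check_frame(X)
        return np.asarray(weighted_score(X, self.weights_)).reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.array(["grs"])

    @staticmethod
    def _check_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named dosage columns")
        return X


class OxidativeStressScorer(BaseEstimator, TransformerMixin):
    """Tertile-based weighted oxidative stress score.

    ``fit(X, y)``: derive (or accept fixed) tertile cutpoints per biomarker,
    code each biomarker 0/1/2 by tertile, then estimate the weights with one
    joint logistic fit of the outcome on the three tertile scores.
    ``transform(X)``: tertile-code with the fitted cutpoints and return the
    weighted sum as an (n, 1) array.

    Parameters
    ----------
    biomarker_cols : biomarker column names (default the MDA / ox-LDL /
        8-epi-PGF2a triplet).
    cutoffs : optional mapping name -> (c1, c2) of fixed published
        cutpoints; None derives tertiles from the fitting data.
    covariate_cols : optional adjustment covariates for the weight fit
        (default none: the joint model contains the tertile scores only).
    unweighted : use unit weights (score = plain tertile sum) instead of
        fitted coefficients.

    Attributes
    ----------
    cutoffs_ : dict name -> TertileCutoffs
    weights_ : ScoreWeights
    """

    def __init__(self, biomarker_cols: Sequence[str] = ("mda", "ox_ldl", "epi_pgf2a"),
                 cutoffs: Optional[Mapping[str, tuple[float, float]]] = None,
                 covariate_cols: Sequence[str] = (),
                 unweighted: bool = False):
        self.biomarker_cols = biomarker_cols
        self.cutoffs = cutoffs
        self.covariate_cols = covariate_cols
        self.unweighted = unweighted

    def fit(self, X: pd.DataFrame, y):
        X = GeneticRiskScorer._check_frame(X)
        cols = list(self.biomarker_cols)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"biomarkers not in X: {missing}")
        if self.cutoffs is not None:
            self.cutoffs_ = {c: TertileCutoffs(c, *self.cutoffs[c], source="fixed")
                             for c in cols}
        else:
            self.cutoffs_ = {c: tertile_cutoffs(X[c], biomarker=c) for c in cols}
        tert = self._tertile_frame(X)
        if self.unweighted:
            self.weights_ = ScoreWeights({c: 1.0 for c in cols}, "tertile_score")
        else:
            cohort = tert.copy()
            covs = [c for c in self.covariate_cols if c in X.columns]
            for c in covs:
                cohort[c] = X[c].to_numpy()
            cohort["label"] = np.asarray(y)
            self.weights_ = fit_component_weights(cohort, cols, "tertile_score", covs)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = GeneticRiskScorer._check_frame(X)
        tert = self._tertile_frame(X)
        return np.asarray(weighted_score(tert, self.weights_)).reshape(-1, 1)

    def tertile_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject 0/1/2 tertile codes using the fitted cutpoints."""
        check_is_fitted(self, "cutoffs_")
        return self._tertile_frame(GeneticRiskScorer._check_frame(X))

    def get_feature_names_out(self, input_features=None):
        return np.array(["oss"])

    def _tertile_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {c: assign_tertile(X[c].to_numpy(), self.cutoffs_[c])
             for c in self.biomarker_cols})
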