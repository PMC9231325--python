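"""GRS / OSS construction: tertiles, weights, score arithmetic, estimators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone
from sklearn.exceptions import NotFittedError
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from grsoss.panel import reference_oss_cutoffs
from grsoss.scoring import (GeneticRiskScorer, OxidativeStressScorer,
                            ScoreWeights, TertileCutoffs, assign_tertile,
                            fit_component_weights, tertile_cutoffs,
                            weighted_score)


class TestTertileCutoffs:
    def test_order_statistic_interpolation_on_1_to_9(self):
        # h = (n-1)p + 1: 1/3 and 2/3 quantiles of 1..9 are 11/3 and 19/3
        cuts = tertile_cutoffs(np.arange(1.0, 10.0))
        assert cuts.c1 == pytest.approx(11 / 3)
        assert cuts.c2 == pytest.approx(19 / 3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tertile_cutoffs(np.full(10, 3.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            tertile_cutoffs([1.0, 2.0])

    # well-spaced values: quantile interpolation between adjacent order
    # statistics must itself be representable strictly between them
    @given(st.lists(st.integers(-10**4, 10**4), min_size=6, max_size=60,
                    unique=True))
    def test_tertile_counts_invariant_under_monotone_transform(self, ints):
        v = np.asarray(ints, dtype=float) / 8
        scores_raw = assign_tertile(v, tertile_cutoffs(v))
        g = v ** 3 + v  # strictly monotone, nonlinear
        scores_g = assign_tertile(g, tertile_cutoffs(g))
        np.testing.assert_array_equal(scores_raw, scores_g)

    def test_cutoffs_transform_only_linearly(self):
        v = np.arange(1.0, 10.0)
        lin = tertile_cutoffs(3 * v + 1)
        assert lin.c1 == pytest.approx(3 * 11 / 3 + 1)
        sq = tertile_cutoffs(v ** 2)
        assert sq.c1 != pytest.approx((11 / 3) ** 2)

    @given(st.lists(st.integers(-10**4, 10**4), min_size=9, max_size=45,
                    unique=True))
    def test_partition_is_balanced_on_tie_free_samples(self, ints):
        v = np.asarray(ints, dtype=float) / 8
        scores = assign_tertile(v, tertile_cutoffs(v))
        counts = np.bincount(scores, minlength=3)
        assert counts.max() - counts.min() <= 1


class TestAssignTertile:
    def test_published_cutpoints_code_the_group_means(self):
        cuts = reference_oss_cutoffs()
        ox = TertileCutoffs("ox_ldl", *cuts["ox_ldl"])
        assert (ox.c1, ox.c2) == (36.34, 51.76)
        assert assign_tertile(45.2, ox) == 1   # control-group mean ox-LDL
        mda = TertileCutoffs("mda", *cuts["mda"])
        assert assign_tertile(10.4, mda) == 2  # case-group mean MDA
        epi = TertileCutoffs("epi_pgf2a", *cuts["epi_pgf2a"])
        assert assign_tertile(1559.7, epi) == 1

    def test_boundaries_are_upper_inclusive(self):
        cuts = TertileCutoffs("x", 1.0, 2.0)
        assert assign_tertile(1.0, cuts) == 0   # exactly c1 -> lower tertile
        assert assign_tertile(2.0, cuts) == 1
        assert assign_tertile(2.0000001, cuts) == 2

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            assign_tertile(float("nan"), TertileCutoffs("x", 1.0, 2.0))

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="c1 < c2"):
            TertileCutoffs("x", 2.0, 1.0)


class TestWeightedScore:
    def test_all_zero_components_score_zero(self):
        w = ScoreWeights({"a": 0.3, "b": -0.7}, "allele_dosage")
        assert weighted_score({"a": 0, "b": 0}, w) == 0.0

    def test_uniform_weights_scale_total_dosage(self):
        w = ScoreWeights({f"s{i}": 0.25 for i in range(6)}, "allele_dosage")
        vals = {"s0": 2, "s1": 2, "s2": 1, "s3": 1, "s4": 1, "s5": 0}  # total 7
        assert weighted_score(vals, w) == pytest.approx(7 * 0.25)

    def test_unit_weights_give_plain_tertile_sum(self):
        w = ScoreWeights({"mda": 1.0, "ox_ldl": 1.0, "epi_pgf2a": 1.0},
                         "tertile_score")
        assert weighted_score({"mda": 1, "ox_ldl": 2, "epi_pgf2a": 0}, w) == 3.0

    def test_missing_component_named_in_error(self):
        w = ScoreWeights({"a": 1.0, "b": 1.0}, "allele_dosage")
        with pytest.raises(KeyError, match="b"):
            weighted_score({"a": 1}, w)

    def test_dataframe_input_vectorizes(self):
        w = ScoreWeights({"a": 2.0, "b": -1.0}, "allele_dosage")
        df = pd.DataFrame({"a": [0, 1, 2], "b": [2, 1, 0]})
        np.testing.assert_allclose(weighted_score(df, w), [-2.0, 1.0, 4.0])

    def test_score_is_monotone_in_dosage_with_positive_weights(self):
        w = ScoreWeights({"a": 0.5, "b": 0.2}, "allele_dosage")
        profiles = list(itertools.product([0, 1, 2], repeat=2))
        scores = {p: weighted_score(dict(zip("ab", p)), w) for p in profiles}
        for (a1, b1) in profiles:
            for (a2, b2) in profiles:
                if a1 <= a2 and b1 <= b2 and (a1, b1) != (a2, b2):
                    assert scores[(a1, b1)] < scores[(a2, b2)]

    def test_extrema_attained_at_uniform_profiles(self):
        w = ScoreWeights({"mda": 0.54, "ox_ldl": 0.22, "epi_pgf2a": 0.13},
                         "tertile_score")
        scores = [weighted_score(dict(zip(("mda", "ox_ldl", "epi_pgf2a"), p)), w)
                  for p in itertools.product([0, 1, 2], repeat=3)]
        assert min(scores) == weighted_score(
            {"mda": 0, "ox_ldl": 0, "epi_pgf2a": 0}, w)
        assert max(scores) == weighted_score(
            {"mda": 2, "ox_ldl": 2, "epi_pgf2a": 2}, w)

    def test_subject_ordering_invariant_to_weight_rescaling(self, rng):
        df = pd.DataFrame(rng.integers(0, 3, size=(50, 3)), columns=list("abc"))
        w1 = ScoreWeights({"a": 0.4, "b": 0.1, "c": 0.9}, "allele_dosage")
        # power-of-two factor: rescaled sums are exact, so ties stay ties
        w2 = ScoreWeights({k: 4.0 * v for k, v in w1.weights.items()},
                          "allele_dosage")
        s1, s2 = weighted_score(df, w1), weighted_score(df, w2)
        np.testing.assert_array_equal(np.argsort(s1, kind="stable"),
                                      np.argsort(s2, kind="stable"))

    def test_nonfinite_weight_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ScoreWeights({"a": np.inf}, "allele_dosage")


class TestFitComponentWeights:
    def test_null_cohort_weights_near_zero(self, rng):
        n = 5000
        cohort = pd.DataFrame({
            "label": rng.integers(0, 2, n),
            "s1": rng.binomial(2, 0.4, n),
            "s2": rng.binomial(2, 0.6, n),
        })
        w = fit_component_weights(cohort, ["s1", "s2"], "allele_dosage")
        se_approx = 1 / np.sqrt(n * 0.5 * 0.5)  # dosage variance ~ 2p(1-p)
        for beta in w.weights.values():
            assert abs(beta) < 3 * se_approx * 2

    def test_known_effects_recovered(self, rng):
        # outcome generated from a logistic model with known per-allele betas
        n, betas = 20_000, {"s1": 0.4, "s2": -0.3}
        dos = {k: rng.binomial(2, 0.5, n) for k in betas}
        lin = -0.2 + sum(b * dos[k] for k, b in betas.items())
        y = rng.random(n) < 1 / (1 + np.exp(-lin))
        cohort = pd.DataFrame({"label": y.astype(int), **dos})
        w = fit_component_weights(cohort, list(betas), "tertile_score")  # joint
        for k, b in betas.items():
            assert w.weights[k] == pytest.approx(b, abs=0.06)

    def test_missing_component_rejected(self, cohort_small):
        with pytest.raises(KeyError, match="nope"):
            fit_component_weights(cohort_small, ["nope"], "allele_dosage")

    def test_unknown_kind_rejected(self, cohort_small):
        with pytest.raises(ValueError, match="component_kind"):
            fit_component_weights(cohort_small, ["rs1260326"], "whatever")


class TestEstimators:
    def test_grs_fit_transform_shapes(self, cohort_small):
        grs = GeneticRiskScorer(snp_cols=["rs1260326", "rs10830963"])
        out = grs.fit(cohort_small, cohort_small["label"]).transform(cohort_small)
        assert out.shape == (len(cohort_small), 1)
        assert set(grs.weights_.weights) == {"rs1260326", "rs10830963"}

    def test_grs_requires_fit_before_transform(self, cohort_small):
        with pytest.raises(NotFittedError):
            GeneticRiskScorer().transform(cohort_small)

    def test_oss_learns_cutoffs_and_weights(self, cohort_small):
        oss = OxidativeStressScorer()
        oss.fit(cohort_small, cohort_small["label"])
        for name, cuts in oss.cutoffs_.items():
            assert cuts.c1 < cuts.c2
            assert cuts.source == "data_derived"
        out = oss.transform(cohort_small)
        assert out.shape == (len(cohort_small), 1)

    def test_oss_fixed_cutoffs_respected(self, cohort_small):
        fixed = reference_oss_cutoffs()
        oss = OxidativeStressScorer(cutoffs=fixed)
        oss.fit(cohort_small, cohort_small["label"])
        assert oss.cutoffs_["mda"].c1 == 7.44
        assert oss.cutoffs_["mda"].source == "fixed"

    def test_oss_unweighted_is_plain_tertile_sum(self, cohort_small):
        oss = OxidativeStressScorer(unweighted=True)
        oss.fit(cohort_small, cohort_small["label"])
        tert = oss.tertile_scores(cohort_small)
        np.testing.assert_allclose(oss.transform(cohort_small)[:, 0],
                                   tert.sum(axis=1))

    def test_estimators_clone_and_compose_in_pipeline(self, cohort_small):
        pipe = Pipeline([
            ("oss", OxidativeStressScorer()),
            ("clf", LogisticRegression()),
        ])
        clone(pipe)  # sklearn param contract
        y = cohort_small["label"].to_numpy()
        pipe.fit(cohort_small, y)
        proba = pipe.predict_proba(cohort_small)
        assert proba.shape == (len(cohort_small), 2)

    def test_grs_get_params_round_trip(self):
        grs = GeneticRiskScorer(snp_cols=["a"], joint=True)
        params = grs.get_params()
        assert params["joint"] is True
        grs2 = GeneticRiskScorer(**params)
        assert grs2.snp_cols == ["a"]
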