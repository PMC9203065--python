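"""OLS fitting, backward elimination, CV majority-vote selection."""

import numpy as np
import pandas as pd
import pytest

from proofbp.cohort import CohortConfig, generate_cohort
from proofbp.development import (
    DevelopmentConfig,
    ProofBPUSEstimator,
    RankDeficiencyError,
    backward_eliminate,
    default_candidate_terms,
    fit_least_squares,
    internal_validate,
    kfold_majority_select,
    seeded_folds,
)
from proofbp.model import TermSpec, resolve_term


class TestOLS:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"intercept": 1.0, "a": rng.normal(size=200),
                          "b": rng.normal(size=200)})
        beta = np.array([2.0, -1.5, 0.7])
        y = X.to_numpy() @ beta
        fit = fit_least_squares(X, y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert abs(fit.resid.mean()) < 1e-10  # residual mean 0 with intercept

    def test_intercept_only_constant(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        fit = fit_least_squares(X, np.full(10, 3.25))
        assert fit.params["intercept"] == pytest.approx(3.25)

    def test_two_point_hand_solution(self):
        X = pd.DataFrame({"intercept": [1.0, 1.0, 1.0], "x": [0.0, 1.0, 2.0]})
        fit = fit_least_squares(X, [1.0, 3.0, 5.0])
        assert fit.params["intercept"] == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_rank_deficiency_names_collinear_terms(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = pd.DataFrame({"intercept": 1.0, "a": a, "twice_a": 2 * a})
        with pytest.raises(RankDeficiencyError, match="twice_a"):
            fit_least_squares(X, rng.normal(size=50))


def _design(n, rng):
    return pd.DataFrame({
        "intercept": np.ones(n),
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "null": rng.normal(size=n),
    })


class TestBackwardElimination:
    def test_null_candidate_removed_in_most_seeds(self):
        removed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _design(2000, rng)
            y = 1.0 + 0.5 * X["x1"] + rng.normal(size=2000)
            sel = backward_eliminate(X, y, list(X.columns), ["intercept", "x1"])
            removed += "null" not in sel
        assert removed >= 18  # retention probability ~ alpha = 0.05

    def test_strong_candidate_always_retained(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = _design(2000, rng)
            y = 1.0 + 1.0 * X["x2"] + rng.normal(size=2000)  # 1 SD standardized effect
            sel = backward_eliminate(X, y, list(X.columns), ["intercept"])
            assert "x2" in sel

    def test_prespecified_never_removed_even_when_null(self):
        rng = np.random.default_rng(5)
        X = _design(500, rng)
        y = rng.normal(size=500)  # everything null
        sel = backward_eliminate(X, y, list(X.columns), ["intercept", "x1"])
        assert "x1" in sel and "intercept" in sel

    def test_hierarchy_protects_main_while_square_survives(self):
        rng = np.random.default_rng(8)
        n = 3000
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": 1.0, "x": x, "x_sq": x**2})
        y = 1.0 + 0.8 * x**2 + rng.normal(size=n)  # pure curvature, no main effect
        terms = [TermSpec("intercept"), TermSpec("x", ("x",), "identity"),
                 TermSpec("x_sq", ("x",), "square")]
        sel = backward_eliminate(X, y, list(X.columns), ["intercept"],
                                 term_specs=terms, hierarchy_rule=True)
        assert "x_sq" in sel and "x" in sel  # main kept under its surviving square
        sel_free = backward_eliminate(X, y, list(X.columns), ["intercept"],
                                      term_specs=terms, hierarchy_rule=False)
        assert "x" not in sel_free


class TestFolds:
    def test_partition_near_equal_and_disjoint(self):
        rng = np.random.default_rng(0)
        folds = seeded_folds([f"p{i}" for i in range(103)], 10, rng)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
        all_ids = np.concatenate(folds)
        assert len(np.unique(all_ids)) == 103

    def test_partition_invariant_to_row_order(self, small_cohort):
        cohort, _ = small_cohort
        shuffled = cohort.sample(frac=1.0, random_state=3).reset_index(drop=True)
        terms = ["intercept", "age", "male", "first_office_sbp", "bmi"]
        a = internal_validate(cohort, "sbp", terms, k_folds=5, seed=11)
        b = internal_validate(shuffled, "sbp", terms, k_folds=5, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestMajoritySelection:
    def test_vote_threshold_is_more_than_half(self):
        cfg = DevelopmentConfig(k_folds=10)
        assert cfg.threshold() == 6  # 6 of 10 -> included; 5 of 10 -> excluded
        with pytest.raises(ValueError):
            DevelopmentConfig(k_folds=10, majority_threshold=5).threshold()

    def test_noiseless_cohort_recovers_exact_support(self):
        truth = {"intercept": 4.0, "first_office_sbp": -0.3, "age": 0.1,
                 "bmi": 0.5, "antihypertensive_use": -3.0}
        cohort, _ = generate_cohort(CohortConfig(
            n_participants=800, seed=21, noise_sd_sbp=0.0, true_beta_sbp=truth))
        per_fold, votes, final = kfold_majority_select(
            cohort, "sbp", DevelopmentConfig(seed=21))
        support = {"intercept", "age", "male", "first_office_sbp",
                   "bmi", "antihypertensive_use"}  # truth + prespecified
        assert set(final) == support
        for sel in per_fold.values():
            assert support <= set(sel)

    def test_internal_validation_zero_noise_is_exact(self):
        truth = {"intercept": 2.0, "age": 0.05}
        cohort, _ = generate_cohort(CohortConfig(
            n_participants=400, seed=31, noise_sd_sbp=0.0, true_beta_sbp=truth))
        ho = internal_validate(cohort, "sbp", ["intercept", "age", "male",
                                               "first_office_sbp"], seed=31)
        np.testing.assert_allclose(ho["predicted"], ho["observed"], atol=1e-8)
        assert ho["id"].is_unique and len(ho) == 400

    def test_estimator_reproducible_and_sklearn_compatible(self, default_cohort):
        from sklearn.base import clone

        cohort, _ = default_cohort
        est = ProofBPUSEstimator(outcome="dbp", random_state=1)
        assert clone(est).get_params() == est.get_params()
        sub = cohort.head(600)
        a = clone(est).fit(sub)
        b = clone(est).fit(sub)
        assert a.final_terms_ == b.final_terms_
        assert a.model_.coefficients == b.model_.coefficients
        pd.testing.assert_frame_equal(a.heldout_predictions_, b.heldout_predictions_)

    def test_selection_and_validation_partitions_are_independent(self, developed_sbp):
        # the two CV stages consume different substreams: selection folds and
        # validation folds must not be forced equal
        ho = developed_sbp.heldout_predictions_
        assert ho["fold"].nunique() == 10
        assert ho["id"].is_unique


def test_default_candidates_include_prespecified_and_derived_terms():
    terms = default_candidate_terms("sbp")
    names = [t.name for t in terms]
    for req in ("intercept", "age", "male", "first_office_sbp"):
        assert req in names
    assert "age_sq" in names and "first_office_sbp_x_bmi" in names
    assert "race_black" not in names
    assert "race_black" in [t.name for t in default_candidate_terms("sbp", include_race=True)]
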