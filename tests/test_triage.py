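"""Tri-state referral rule, grid enumeration and the range optimizer."""

import itertools

import numpy as np
import pandas as pd
import pytest

from proofbp.classification import BPThresholds
from proofbp.triage import (
    ReferralRangeOptimizer,
    ReferralRangePair,
    TriageDecision,
    acc_aha_decide,
    decide,
    decide_many,
    enumerate_candidate_ranges,
    evaluate_ranges,
    optimize_ranges,
    phenotype_by_recommendation,
)

RANGES = ReferralRangePair(120, 135, 75, 85)  # displays 120-134/75-84

# below/within/above per axis -> decision under precedence above > within > below
_LEVELS = {"below": (118.0, 70.0), "within": (128.0, 78.0), "above": (140.0, 90.0)}


def _expected(sbp_state, dbp_state):
    if "above" in (sbp_state, dbp_state):
        return TriageDecision.ASSUME_HYPERTENSION
    if "within" in (sbp_state, dbp_state):
        return TriageDecision.REFER
    return TriageDecision.ASSUME_NORMOTENSION


class TestDecide:
    @pytest.mark.parametrize(
        "sbp_state,dbp_state", list(itertools.product(_LEVELS, _LEVELS))
    )
    def test_truth_table_all_nine_combinations(self, sbp_state, dbp_state):
        sbp = _LEVELS[sbp_state][0]
        dbp = _LEVELS[dbp_state][1]
        assert decide(sbp, dbp, RANGES) is _expected(sbp_state, dbp_state)

    def test_window_boundaries_closed_low_open_high(self):
        assert decide(120.0, 70.0, RANGES) is TriageDecision.REFER      # at low edge
        assert decide(135.0, 70.0, RANGES) is TriageDecision.ASSUME_HYPERTENSION
        assert decide(119.999, 74.999, RANGES) is TriageDecision.ASSUME_NORMOTENSION

    def test_edge_threshold_never_assumed_normotensive(self):
        r = ReferralRangePair(130, 150, 80, 100)
        assert decide(130.0, 60.0, r) is TriageDecision.REFER

    def test_display_convention(self):
        assert RANGES.display == "120-134/75-84"
        assert ReferralRangePair(125, 135, 75, 85).display == "125-134/75-84"


class TestEnumeration:
    def test_grid_counts(self):
        sbp = enumerate_candidate_ranges(120, 150, 5)
        dbp = enumerate_candidate_ranges(70, 100, 5)
        assert len(sbp) == 21  # C(7,2) over 7 gridpoints
        assert len(dbp) == 21
        assert len(sbp) * len(dbp) == 441
        assert (120, 125) in sbp and (120, 150) in sbp

    def test_step_must_divide_span(self):
        with pytest.raises(ValueError, match="divide"):
            enumerate_candidate_ranges(120, 150, 7)


def _tables(pred_pairs, obs_pairs):
    ids = [f"p{i}" for i in range(len(pred_pairs))]
    pred = pd.DataFrame({"id": ids, "pred_sbp": [p[0] for p in pred_pairs],
                         "pred_dbp": [p[1] for p in pred_pairs]})
    obs = pd.DataFrame({"id": ids, "awake_sbp": [o[0] for o in obs_pairs],
                        "awake_dbp": [o[1] for o in obs_pairs]})
    return pred, obs


class TestEvaluate:
    def test_hand_worked_four_participant_example(self):
        pred, obs = _tables(
            [(118, 70), (140, 86), (128, 78), (136, 70)],
            [(125, 70), (131, 82), (128, 78), (126, 70)],
        )
        ev = evaluate_ranges(pred, obs, RANGES)
        assert ev.decision_counts == {
            "assume_normotension": 1, "refer": 1, "assume_hypertension": 2
        }
        assert ev.prop_referred == pytest.approx(0.25)
        # one of the 3 not-referred is wrong: assumed hypertensive, observed 126/70
        assert ev.prop_misclassified_among_not_referred == pytest.approx(1 / 3)

    def test_perfect_predictor_never_misclassifies(self):
        rng = np.random.default_rng(0)
        obs_pairs = [(rng.uniform(100, 160), rng.uniform(60, 100)) for _ in range(100)]
        pred, obs = _tables(obs_pairs, obs_pairs)
        for r in [RANGES, ReferralRangePair(125, 150, 80, 95)]:
            ev = evaluate_ranges(pred, obs, r)
            assert ev.prop_misclassified_among_not_referred == 0.0
            assert ev.feasible

    def test_everyone_referred_guard_defines_zero_misclassification(self):
        pred, obs = _tables([(128, 78)] * 5, [(150, 95)] * 5)
        ev = evaluate_ranges(pred, obs, RANGES)
        assert ev.prop_referred == 1.0
        assert ev.prop_misclassified_among_not_referred == 0.0

    def test_counts_sum_to_cohort_size(self, predictions_default, observed_default):
        ev = evaluate_ranges(predictions_default, observed_default, RANGES)
        assert sum(ev.decision_counts.values()) == ev.n == len(predictions_default)

    def test_id_mismatch_rejected(self):
        pred, obs = _tables([(120, 80)], [(120, 80)])
        obs["id"] = ["other"]
        with pytest.raises(ValueError, match="mismatched ids"):
            evaluate_ranges(pred, obs, RANGES)


def brute_force_optimum(pred, obs, limit=0.20):
    """Independent exhaustive re-evaluation of all 441 pairs."""
    best = None
    for slo in range(120, 150, 5):
        for shi in range(slo + 5, 151, 5):
            for dlo in range(70, 100, 5):
                for dhi in range(dlo + 5, 101, 5):
                    dec = []
                    for _, row in pred.merge(obs, on="id").iterrows():
                        if row.pred_sbp >= shi or row.pred_dbp >= dhi:
                            dec.append("H")
                        elif row.pred_sbp >= slo or row.pred_dbp >= dlo:
                            dec.append("R")
                        else:
                            dec.append("N")
                    m = pred.merge(obs, on="id")
                    htn = (m.awake_sbp >= 130) | (m.awake_dbp >= 80)
                    dec = np.array(dec)
                    not_ref = dec != "R"
                    mis = ((dec == "N") & htn) | ((dec == "H") & ~htn)
                    n_nr = not_ref.sum()
                    pm = mis.sum() / n_nr if n_nr else 0.0
                    if pm < limit:
                        key = (np.mean(dec == "R"), pm, (shi - slo) + (dhi - dlo), slo, dlo)
                        if best is None or key < best[0]:
                            best = (key, (slo, shi, dlo, dhi))
    return best


class TestOptimizer:
    def test_matches_brute_force_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(12)
        for trial in range(10):
            n = 120
            obs_sbp = rng.normal(128, 12, n)
            obs_dbp = rng.normal(78, 8, n)
            pred_pairs = list(zip(obs_sbp + rng.normal(0, 6, n),
                                  obs_dbp + rng.normal(0, 5, n)))
            obs_pairs = list(zip(obs_sbp, obs_dbp))
            pred, obs = _tables(pred_pairs, obs_pairs)
            best, grid = optimize_ranges(pred, obs)
            oracle = brute_force_optimum(pred, obs)
            assert oracle is not None and best.feasible
            r = best.ranges
            assert (r.sbp_low, r.sbp_high, r.dbp_low, r.dbp_high) == oracle[1]
            assert len(grid) == 441

    def test_degenerate_cohort_yields_zero_referral(self):
        pred, obs = _tables([(128, 78)] * 20, [(128, 78)] * 20)
        best, _ = optimize_ranges(pred, obs)
        assert best.prop_referred == 0.0
        assert best.prop_misclassified_among_not_referred == 0.0

    def test_constraint_satisfied_whenever_feasible(self, predictions_default,
                                                    observed_default):
        best, grid = optimize_ranges(predictions_default, observed_default)
        assert best.feasible
        assert best.prop_misclassified_among_not_referred < 0.20
        feas = grid[grid.feasible]
        assert best.prop_referred == pytest.approx(feas.prop_referred.min())

    def test_monotonicity_enlarging_windows_never_decreases_referral(
        self, predictions_default, observed_default
    ):
        _, grid = optimize_ranges(predictions_default, observed_default)
        g = grid.set_index(["sbp_low", "sbp_high", "dbp_low", "dbp_high"])
        for (slo, shi, dlo, dhi), row in g.iterrows():
            for bigger in [(slo - 5, shi, dlo, dhi), (slo, shi + 5, dlo, dhi),
                           (slo, shi, dlo - 5, dhi), (slo, shi, dlo, dhi + 5)]:
                if bigger in g.index:
                    assert g.loc[bigger, "prop_referred"] >= row["prop_referred"] - 1e-12

    def test_estimator_wrapper(self, predictions_default, observed_default):
        opt = ReferralRangeOptimizer().fit(predictions_default, observed_default)
        assert opt.feasible_
        dec = opt.predict(predictions_default)
        assert set(np.unique(dec)) <= {t.value for t in TriageDecision}


class TestAccAha:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (140, 85, TriageDecision.REFER),
            (165, 85, TriageDecision.ASSUME_HYPERTENSION),
            (118, 70, TriageDecision.ASSUME_NORMOTENSION),
        ],
    )
    def test_untreated_examples(self, sbp, dbp, expected):
        assert acc_aha_decide(sbp, dbp, treated=False) is expected

    def test_vectorized_matches_scalar(self):
        s = np.array([140.0, 165.0, 118.0])
        d = np.array([85.0, 85.0, 70.0])
        out = acc_aha_decide(s, d, np.zeros(3, dtype=bool))
        assert list(out) == ["refer", "assume_hypertension", "assume_normotension"]


class TestPhenotypeTable:
    def test_perfect_predictor_pure_rows_and_normalization(self, classified_default):
        classified = classified_default
        # perfect predictor: predicted = observed awake BP
        pred = classified.rename(columns={"awake_sbp": "pred_sbp",
                                          "awake_dbp": "pred_dbp"})
        decisions = pd.DataFrame({
            "id": classified["id"],
            "decision": decide_many(pred["pred_sbp"], pred["pred_dbp"], RANGES),
        })
        table = phenotype_by_recommendation(classified, decisions, n_boot=30, seed=0)
        phen_rows = table[table.measure != "share_of_stratum"]
        sums = phen_rows.groupby(["treated", "decision"])["percent"].sum()
        occupied = table[(table.measure == "share_of_stratum") & (table.percent > 0)]
        for (treated, dec) in zip(occupied.treated, occupied.decision):
            assert sums[(treated, dec)] == pytest.approx(100.0)
        # with a perfect predictor nobody assumed normotensive is hypertensive
        normo = table[(table.decision == "assume_normotension")
                      & (table.measure == "sustained_hypertension")]
        assert (normo.percent == 0).all()
        # assume-hypertension rows dominated by sustained hypertension
        ah = table[(table.decision == "assume_hypertension")
                   & (table.measure != "share_of_stratum")]
        for treated, grp in ah.groupby("treated"):
            top = grp.sort_values("percent").iloc[-1]
            assert top.measure in ("sustained_hypertension",)
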