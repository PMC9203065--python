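"""Tri-state referral rule, referral-range grid search and tabulations.

Given predicted out-of-office SBP/DBP and a pair of referral windows, each
person is triaged: assume out-of-office hypertension when either prediction
is at/above its window, otherwise refer for out-of-office measurement when
either prediction falls inside its window, otherwise assume normotension
(precedence above > within > below makes the three states exhaustive and
mutually exclusive).  Windows are half-open ``[low, high)`` on a 5 mm Hg
grid; the display string "120-134" means the window [120, 135).

The optimizer exhaustively evaluates every SBP x DBP window pair on the
grid (SBP 120-150, DBP 70-100 in 5 mm Hg steps gives 21 x 21 = 441 pairs)
and returns the feasible pair — misclassification among the not-referred
below the limit (default 20%) — with the smallest referred proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .classification import BPThresholds, Phenotype, is_hypertensive
from .metrics import bca_interval

__all__ = [
    "TriageDecision",
    "ReferralRangePair",
    "RangeEvaluation",
    "decide",
    "decide_many",
    "enumerate_candidate_ranges",
    "evaluate_ranges",
    "optimize_ranges",
    "acc_aha_decide",
    "phenotype_by_recommendation",
    "ReferralRangeOptimizer",
    "DEFAULT_ACC_AHA_BANDS",
    "DEFAULT_REFERRAL_RANGES",
]


class TriageDecision(str, Enum):
    ASSUME_NORMOTENSION = "assume_normotension"
    REFER = "refer"
    ASSUME_HYPERTENSION = "assume_hypertension"


@dataclass(frozen=True)
class ReferralRangePair:
    """SBP and DBP referral windows, each half-open [low, high)."""

    sbp_low: float
    sbp_high: float
    dbp_low: float
    dbp_high: float

    def __post_init__(self) -> None:
        if not (self.sbp_low < self.sbp_high and self.dbp_low < self.dbp_high):
            raise ValueError("window low must be below high on both axes")

    @property
    def display(self) -> str:
        return (f"{self.sbp_low:g}-{self.sbp_high - 1:g}/"
                f"{self.dbp_low:g}-{self.dbp_high - 1:g}")

    @property
    def total_width(self) -> float:
        return (self.sbp_high - self.sbp_low) + (self.dbp_high - self.dbp_low)


#: Referral windows on the scale reported for US adults (predicted
#: out-of-office 125-134/75-84 mm Hg): a usable default deployment rule when
#: no cohort is at hand to re-optimize on.
DEFAULT_REFERRAL_RANGES = ReferralRangePair(125.0, 135.0, 75.0, 85.0)


def decide_many(pred_sbp, pred_dbp, ranges: ReferralRangePair) -> np.ndarray:
    """Vectorized tri-state decision (array of TriageDecision values)."""
    s = np.asarray(pred_sbp, dtype=float)
    d = np.asarray(pred_dbp, dtype=float)
    above = (s >= ranges.sbp_high) | (d >= ranges.dbp_high)
    within = (s >= ranges.sbp_low) | (d >= ranges.dbp_low)
    return np.where(above, TriageDecision.ASSUME_HYPERTENSION.value,
                    np.where(within, TriageDecision.REFER.value,
                             TriageDecision.ASSUME_NORMOTENSION.value))


def decide(pred_sbp: float, pred_dbp: float, ranges: ReferralRangePair) -> TriageDecision:
    return TriageDecision(decide_many([pred_sbp], [pred_dbp], ranges)[0])


def enumerate_candidate_ranges(grid_low: float, grid_high: float,
                               step: float) -> list[tuple[float, float]]:
    """All [L, H) windows with both endpoints on the grid and L < H."""
    if grid_low >= grid_high:
        raise ValueError("grid_low must be below grid_high")
    span = grid_high - grid_low
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide the span {span}")
    points = [grid_low + i * step for i in range(int(round(n_steps)) + 1)]
    return [(lo, hi) for i, lo in enumerate(points) for hi in points[i + 1:]]


@dataclass
class RangeEvaluation:
    ranges: ReferralRangePair
    prop_referred: float
    prop_misclassified_among_not_referred: float
    decision_counts: dict[str, int]
    feasible: bool
    n: int


def _aligned(predictions: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    merged = predictions.merge(observed, on="id", how="inner", validate="one_to_one")
    if len(merged) != len(predictions) or len(merged) != len(observed):
        raise ValueError("prediction and observation tables have mismatched ids")
    return merged


def evaluate_ranges(predictions: pd.DataFrame, observed: pd.DataFrame,
                    ranges: ReferralRangePair,
                    thresholds: BPThresholds = BPThresholds(),
                    limit: float = 0.20) -> RangeEvaluation:
    """Evaluate one window pair: referred share and misclassification among
    the not-referred.

    ``predictions`` needs columns (id, pred_sbp, pred_dbp); ``observed``
    (id, awake_sbp, awake_dbp).  A not-referred person is misclassified when
    assumed normotensive but observed hypertensive, or assumed hypertensive
    but observed normotensive, at the awake 130/80 thresholds.  With nobody
    unreferred the misclassification proportion is defined as 0.
    """
    m = _aligned(predictions, observed)
    dec = decide_many(m["pred_sbp"], m["pred_dbp"], ranges)
    obs_htn = is_hypertensive(m["awake_sbp"], m["awake_dbp"],
                              thresholds.awake_sbp, thresholds.awake_dbp)
    referred = dec == TriageDecision.REFER.value
    assume_htn = dec == TriageDecision.ASSUME_HYPERTENSION.value
    assume_normo = dec == TriageDecision.ASSUME_NORMOTENSION.value
    mis = (assume_normo & obs_htn) | (assume_htn & ~obs_htn)
    n_not_ref = int((~referred).sum())
    prop_mis = float(mis.sum() / n_not_ref) if n_not_ref else 0.0
    counts = {d.value: int((dec == d.value).sum()) for d in TriageDecision}
    return RangeEvaluation(
        ranges=ranges,
        prop_referred=float(referred.mean()),
        prop_misclassified_among_not_referred=prop_mis,
        decision_counts=counts,
        feasible=prop_mis < limit,
        n=len(m),
    )


def optimize_ranges(predictions: pd.DataFrame, observed: pd.DataFrame,
                    thresholds: BPThresholds = BPThresholds(),
                    sbp_grid: tuple[float, float, float] = (120.0, 150.0, 5.0),
                    dbp_grid: tuple[float, float, float] = (70.0, 100.0, 5.0),
                    limit: float = 0.20) -> tuple[RangeEvaluation, pd.DataFrame]:
    """Exhaustive grid search for the optimal referral window pair.

    Among pairs with misclassification below ``limit``, minimize the referred
    proportion; ties break by lower misclassification, then smaller total
    window width, then lower SBP low edge, then lower DBP low edge.  When no
    pair is feasible, the minimal-misclassification pair is returned with
    ``feasible=False`` and a warning.  Also returns the full audit grid.
    """
    if len(predictions) == 0:
        raise ValueError("empty cohort")
    sbp_windows = enumerate_candidate_ranges(*sbp_grid)
    dbp_windows = enumerate_candidate_ranges(*dbp_grid)
    evals: list[RangeEvaluation] = []
    for slo, shi in sbp_windows:
        for dlo, dhi in dbp_windows:
            evals.append(evaluate_ranges(predictions, observed,
                                         ReferralRangePair(slo, shi, dlo, dhi),
                                         thresholds, limit))
    grid = pd.DataFrame(
        {
            "sbp_low": [e.ranges.sbp_low for e in evals],
            "sbp_high": [e.ranges.sbp_high for e in evals],
            "dbp_low": [e.ranges.dbp_low for e in evals],
            "dbp_high": [e.ranges.dbp_high for e in evals],
            "prop_referred": [e.prop_referred for e in evals],
            "prop_misclassified": [e.prop_misclassified_among_not_referred for e in evals],
            "feasible": [e.feasible for e in evals],
        }
    )

    def key(e: RangeEvaluation):
        return (e.prop_referred, e.prop_misclassified_among_not_referred,
                e.ranges.total_width, e.ranges.sbp_low, e.ranges.dbp_low)

    feasible = [e for e in evals if e.feasible]
    if feasible:
        best = min(feasible, key=key)
        assert best.prop_misclassified_among_not_referred < limit
    else:
        warnings.warn("no feasible window pair; returning minimal-misclassification pair")
        best = min(evals, key=lambda e: (e.prop_misclassified_among_not_referred,
                                         e.prop_referred, e.ranges.total_width,
                                         e.ranges.sbp_low, e.ranges.dbp_low))
    return best, grid


class ReferralRangeOptimizer(BaseEstimator):
    """sklearn-style wrapper: fit the optimal windows, then triage new people.

    Fitted attributes: ``best_``, ``ranges_``, ``grid_``, ``feasible_``.
    """

    def __init__(self, sbp_grid=(120.0, 150.0, 5.0), dbp_grid=(70.0, 100.0, 5.0),
                 limit: float = 0.20, thresholds: BPThresholds = BPThresholds()):
        self.sbp_grid = sbp_grid
        self.dbp_grid = dbp_grid
        self.limit = limit
        self.thresholds = thresholds

    def fit(self, predictions: pd.DataFrame, observed: pd.DataFrame) -> "ReferralRangeOptimizer":
        best, grid = optimize_ranges(predictions, observed, self.thresholds,
                                     self.sbp_grid, self.dbp_grid, self.limit)
        self.best_ = best
        self.ranges_ = best.ranges
        self.grid_ = grid
        self.feasible_ = best.feasible
        return self

    def predict(self, predictions: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "ranges_")
        return decide_many(predictions["pred_sbp"], predictions["pred_dbp"], self.ranges_)


#: Office-BP comparator bands per medication stratum: ((sbp_low, sbp_high),
#: (dbp_low, dbp_high)).  The refer band tops out at 160/100 (referral range
#: up to 159/99); the low edge sits below 130/80 so office-normotensive
#: people can still be screened for masked hypertension.
DEFAULT_ACC_AHA_BANDS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "untreated": ((120.0, 160.0), (75.0, 100.0)),
    "treated": ((120.0, 160.0), (75.0, 100.0)),
}


def acc_aha_decide(mean_office_sbp, mean_office_dbp, treated,
                   bands: Mapping[str, tuple] | None = None) -> np.ndarray:
    """Office-BP guideline comparator: same tri-state logic on mean office BP."""
    bands = bands or DEFAULT_ACC_AHA_BANDS
    s = np.atleast_1d(np.asarray(mean_office_sbp, dtype=float))
    d = np.atleast_1d(np.asarray(mean_office_dbp, dtype=float))
    t = np.atleast_1d(np.asarray(treated)).astype(bool)
    out = np.empty(s.shape, dtype=object)
    for stratum, mask in (("treated", t), ("untreated", ~t)):
        if mask.any():
            (slo, shi), (dlo, dhi) = bands[stratum]
            out[mask] = decide_many(s[mask], d[mask],
                                    ReferralRangePair(slo, shi, dlo, dhi))
    scalar = np.isscalar(mean_office_sbp)
    return TriageDecision(out[0]) if scalar else out.astype(str)


def phenotype_by_recommendation(classified: pd.DataFrame, decisions: pd.DataFrame,
                                n_boot: int = 500, level: float = 0.95,
                                seed: int | None = None) -> pd.DataFrame:
    """Phenotype distribution within each medication stratum x triage decision.

    ``classified`` comes from ``classify_cohort`` (id, phenotype, treated);
    ``decisions`` has (id, decision).  Each row of the output is one cell:
    either the decision's share of its stratum (measure ``share_of_stratum``)
    or a phenotype percentage within (stratum, decision), with BCa intervals
    from resampling participants within the stratum.
    """
    m = classified.merge(decisions, on="id", validate="one_to_one")
    rng = np.random.default_rng(seed)
    phenos = [p.value for p in Phenotype]
    rows = []
    for treated, stratum in m.groupby("treated"):
        dec = stratum["decision"].to_numpy()
        phen = stratum["phenotype"].to_numpy()
        data = np.column_stack([dec, phen])
        n_str = len(stratum)
        for d in [t.value for t in TriageDecision]:
            in_dec = dec == d
            share = 100.0 * in_dec.mean()

            def share_stat(t, d=d):
                return 100.0 * np.mean(t[:, 0] == d)

            if in_dec.sum() == 0:
                rows.append((treated, d, "share_of_stratum", 0.0, 0.0, 0.0))
                for p in phenos:
                    rows.append((treated, d, p, 0.0, 0.0, 0.0))
                continue
            lo, hi = bca_interval(data, share_stat, n_boot=n_boot, level=level, seed=rng)
            rows.append((treated, d, "share_of_stratum", share, lo, hi))
            for p in phenos:
                pct = 100.0 * np.mean(phen[in_dec] == p)

                def cell_stat(t, d=d, p=p):
                    sel = t[:, 0] == d
                    if not sel.any():
                        return 0.0
                    return 100.0 * np.mean(t[sel, 1] == p)

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # empty cells degenerate
                    lo, hi = bca_interval(data, cell_stat, n_boot=n_boot,
                                          level=level, seed=rng)
                rows.append((treated, d, p, pct, lo, hi))
    return pd.DataFrame(rows, columns=["treated", "decision", "measure",
                                       "percent", "ci_low", "ci_high"])
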