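"""Survey-weighted projection of triage recommendations to a population.

Survey persons carry office readings, covariates and a sampling weight but no
awake BP — exactly the deployment setting.  Each triage strategy is either a
pair of difference models with a referral window pair (prediction-based) or
an office-band rule (guideline comparator).  Referred proportions and
population counts are reported per analysis stratum (medication use x office
hypertension status), weighted by the sampling weights; confidence intervals
come from a stratified PSU replicate bootstrap (resampling primary sampling
units with replacement within each design stratum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .classification import BPThresholds, is_hypertensive
from .model import PredictionModel, covariate_frame, MissingCovariateError
from .triage import (
    DEFAULT_ACC_AHA_BANDS,
    ReferralRangePair,
    TriageDecision,
    acc_aha_decide,
    decide_many,
)

__all__ = [
    "ModelStrategy",
    "OfficeBandStrategy",
    "ProjectionReport",
    "weighted_proportion",
    "project_strategies",
]

log = logging.getLogger(__name__)


def weighted_proportion(flags, weights) -> float:
    """Weighted prevalence: sum(w * flag) / sum(w)."""
    f = np.asarray(flags, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.shape != w.shape:
        raise ValueError("flags and weights lengths differ")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return float((w * f).sum() / total)


@dataclass
class ModelStrategy:
    """Prediction-based triage: difference models plus referral windows."""

    model_sbp: PredictionModel
    model_dbp: PredictionModel
    ranges: ReferralRangePair

    def decisions(self, survey: pd.DataFrame) -> np.ndarray:
        pred_sbp = self.model_sbp.predict_out_of_office(survey)
        pred_dbp = self.model_dbp.predict_out_of_office(survey)
        return decide_many(pred_sbp, pred_dbp, self.ranges)


@dataclass
class OfficeBandStrategy:
    """Office-BP band rule (e.g. the 2017 guideline comparator)."""

    bands: Mapping[str, tuple] | None = None

    def decisions(self, survey: pd.DataFrame) -> np.ndarray:
        return acc_aha_decide(survey["mean_office_sbp"], survey["mean_office_dbp"],
                              survey["antihypertensive_use"],
                              self.bands or DEFAULT_ACC_AHA_BANDS)


@dataclass
class ProjectionReport:
    table: pd.DataFrame  # one row per strategy x stratum
    total_population: float
    n_excluded: int


def _prepare_survey(survey: pd.DataFrame, thresholds: BPThresholds) -> tuple[pd.DataFrame, int]:
    df = covariate_frame(survey)
    sbp_cols = [c for c in df.columns if c.startswith("office_sbp_")]
    dbp_cols = [c for c in df.columns if c.startswith("office_dbp_")]
    df["mean_office_sbp"] = df[sbp_cols].mean(axis=1)
    df["mean_office_dbp"] = df[dbp_cols].mean(axis=1)
    df["office_htn"] = is_hypertensive(df["mean_office_sbp"], df["mean_office_dbp"],
                                       thresholds.office_sbp, thresholds.office_dbp).astype(int)
    needed = ["age", "male", "bmi", "mean_office_sbp", "mean_office_dbp", "weight"]
    complete = df[needed].notna().all(axis=1)
    n_excl = int((~complete).sum())
    if n_excl:
        log.warning("excluding %d survey persons with missing covariates", n_excl)
    return df[complete].reset_index(drop=True), n_excl


def _stratum_rows(df: pd.DataFrame) -> list[tuple[int, int, np.ndarray]]:
    out = []
    for (treated, htn), grp in df.groupby(["antihypertensive_use", "office_htn"]):
        out.append((int(treated), int(htn), grp.index.to_numpy()))
    return out


def _psu_bootstrap_indices(df: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """One replicate: resample PSUs with replacement within design strata."""
    parts = []
    for _, grp in df.groupby("stratum"):
        psus = grp["psu"].unique()
        chosen = rng.choice(psus, size=len(psus), replace=True)
        by_psu = {p: grp.index[grp["psu"] == p].to_numpy() for p in psus}
        for p in chosen:
            parts.append(by_psu[p])
    return np.concatenate(parts)


def project_strategies(survey: pd.DataFrame,
                       strategies: Mapping[str, ModelStrategy | OfficeBandStrategy],
                       thresholds: BPThresholds = BPThresholds(),
                       n_boot: int = 200, level: float = 0.95,
                       seed: int | None = None) -> ProjectionReport:
    """Weighted referral projections per strategy and analysis stratum.

    Returns a table with, per (strategy, treated, office_htn): the weighted
    proportions of the three triage decisions, a percentile bootstrap CI for
    the referred proportion, the weighted count referred and the stratum
    population (sum of weights).
    """
    df, n_excl = _prepare_survey(survey, thresholds)
    rng = np.random.default_rng(seed)
    w = df["weight"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("total survey weight must be positive")

    decisions = {}
    for name, strat in strategies.items():
        try:
            decisions[name] = strat.decisions(df)
        except MissingCovariateError as e:
            raise MissingCovariateError(f"strategy {name!r}: {e}") from None

    strata = _stratum_rows(df)
    boot_idx = [_psu_bootstrap_indices(df, rng) for _ in range(n_boot)]

    rows = []
    for name, dec in decisions.items():
        referred = (dec == TriageDecision.REFER.value).astype(float)
        for treated, htn, idx in strata:
            pop = w[idx].sum()
            props = {
                d.value: weighted_proportion((dec[idx] == d.value).astype(float), w[idx])
                for d in TriageDecision
            }
            reps = []
            for bi in boot_idx:
                sel = bi[(df["antihypertensive_use"].to_numpy()[bi] == treated)
                         & (df["office_htn"].to_numpy()[bi] == htn)]
                if sel.size:
                    reps.append(weighted_proportion(referred[sel], w[sel]))
            alpha = (1 - level) / 2
            lo, hi = (np.quantile(reps, [alpha, 1 - alpha]) if reps
                      else (props["refer"], props["refer"]))
            rows.append({
                "strategy": name,
                "treated": treated,
                "office_htn": htn,
                "population": pop,
                "n": int(idx.size),
                "prop_assume_normotension": props["assume_normotension"],
                "prop_referred": props["refer"],
                "prop_assume_hypertension": props["assume_hypertension"],
                "referred_ci_low": float(lo),
                "referred_ci_high": float(hi),
                "count_referred": props["refer"] * pop,
            })
    return ProjectionReport(table=pd.DataFrame(rows),
                            total_population=float(w.sum()),
                            n_excluded=n_excl)
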