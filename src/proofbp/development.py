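"""Development of the US-specific difference model.

The outcome is the awake-minus-first-office BP difference (separately for SBP
and DBP).  Development proceeds in two cross-validation stages:

1. *Selection*: split the cohort into k folds (default 10); on each set of
   k-1 training folds run multistep backward elimination (Wald p-values,
   one removal at a time, main effects protected while their square/product
   terms survive); a candidate enters the final model when selected in more
   than half of the folds.  Age, sex and the first office reading of the
   outcome are prespecified and never eliminated.  Final coefficients come
   from refitting the selected terms on the full cohort.
2. *Internal validation*: an independent k-fold split, refitting the final
   term set on each training portion and predicting out-of-office BP on the
   held-out fold, so every participant gets exactly one held-out prediction.

Exposed both as functions and as the sklearn-style `ProofBPUSEstimator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._rng import substream
from .model import (
    PredictionModel,
    TermSpec,
    covariate_frame,
    design_matrix,
    prespecified_names,
    resolve_term,
)

__all__ = [
    "DevelopmentConfig",
    "DevelopmentResult",
    "OLSFit",
    "RankDeficiencyError",
    "default_candidate_terms",
    "fit_least_squares",
    "backward_eliminate",
    "seeded_folds",
    "kfold_majority_select",
    "internal_validate",
    "develop_model",
    "ProofBPUSEstimator",
]


class RankDeficiencyError(ValueError):
    """Design matrix is not full rank; message names collinear terms."""


def default_candidate_terms(outcome: str, include_race: bool = False) -> list[TermSpec]:
    """Default candidate list: main effects, squares, and products of the
    outcome's first office reading with age, sex, medication use and BMI.

    Derived terms are centered at the default covariate means to tame
    collinearity with their parents; centering only relabels the intercept
    and main-effect coefficients of the *derived* scale, not the model space.
    """
    outcome = outcome.lower()
    mains = [
        "age", "male", "first_office_sbp", "first_office_dbp", "bmi",
        "diabetes", "ckd", "cvd_history", "self_reported_htn",
        "antihypertensive_use", "smoking_former", "smoking_current",
        "alcohol_any", "hs_degree",
    ]
    if include_race:
        mains.append("race_black")
    centers = {"age": 52.0, "bmi": 29.8, "first_office_sbp": 121.8,
               "first_office_dbp": 75.3, "male": 0.0, "antihypertensive_use": 0.0}
    terms = [TermSpec("intercept")] + [resolve_term(m) for m in mains]
    for cov in ("age", "bmi", "first_office_sbp", "first_office_dbp"):
        terms.append(TermSpec(f"{cov}_sq", (cov,), "square", (centers[cov],)))
    fo = f"first_office_{outcome}"
    for cov in ("age", "male", "antihypertensive_use", "bmi"):
        terms.append(TermSpec(f"{fo}_x_{cov}", (fo, cov), "product",
                              (centers[fo], centers[cov])))
    return terms


@dataclass
class DevelopmentConfig:
    """Knobs of the development procedure (spec-level defaults)."""

    k_folds: int = 10
    elimination_alpha: float = 0.05
    majority_threshold: int | None = None  # default: more than half of k_folds
    hierarchy_rule: bool = True
    include_race: bool = False
    seed: int = 0
    candidate_terms: list[TermSpec] | None = None

    def threshold(self) -> int:
        t = self.majority_threshold if self.majority_threshold is not None else self.k_folds // 2 + 1
        if t <= self.k_folds / 2:
            raise ValueError("majority_threshold must exceed k_folds / 2")
        return t


@dataclass
class OLSFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    resid: np.ndarray
    nobs: int


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # greedy scan: columns that do not increase the rank of the prefix
        bad, cols = [], []
        for j, name in enumerate(X.columns):
            trial = A[:, [*cols, j]]
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(j)
            else:
                bad.append(name)
        raise RankDeficiencyError(f"design matrix rank-deficient; collinear terms: {bad}")


def fit_least_squares(X: pd.DataFrame, y: Sequence[float]) -> OLSFit:
    """Ordinary least squares of the BP difference on the term columns."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("design and response lengths differ")
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} terms, got n = {len(y)}")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return OLSFit(params=res.params, bse=res.bse, pvalues=res.pvalues,
                  resid=np.asarray(res.resid), nobs=int(res.nobs))


def _protected_parents(current: Sequence[str], terms: Mapping[str, TermSpec]) -> set[str]:
    """Main-effect names that may not be removed while a derived child is in."""
    protected: set[str] = set()
    for name in current:
        t = terms.get(name)
        if t is not None and t.transform in ("square", "product"):
            for cov in t.base_covariates:
                for other in current:
                    o = terms.get(other)
                    if o is not None and o.transform == "identity" and o.base_covariates == (cov,):
                        protected.add(other)
    return protected


def backward_eliminate(X: pd.DataFrame, y: Sequence[float], candidates: Sequence[str],
                       prespecified: Sequence[str], alpha: float = 0.05,
                       term_specs: Sequence[TermSpec] | None = None,
                       hierarchy_rule: bool = True) -> list[str]:
    """Multistep backward elimination by largest Wald p-value.

    Repeatedly refits and drops the single eligible term with the largest
    p-value above ``alpha``; prespecified terms are never eligible, and with
    the hierarchy rule a main effect is ineligible while any surviving
    square/product term uses its covariate.  Returns the retained term names
    in candidate order.
    """
    missing = set(prespecified) - set(candidates)
    if missing:
        raise ValueError(f"prespecified terms not among candidates: {sorted(missing)}")
    specs = {t.name: t for t in (term_specs or [])}
    y = np.asarray(y, dtype=float)
    y_scale = max(float(np.std(y)), 1e-8)
    col_sd = X.std(axis=0)
    current = list(candidates)
    while True:
        fit = fit_least_squares(X[current], y)
        protected = _protected_parents(current, specs) if hierarchy_rule else set()
        eligible = [t for t in current if t not in prespecified and t not in protected]
        if not eligible:
            return current
        pvals = fit.pvalues[eligible].copy()
        # In a (near-)perfect fit Wald p-values are numerical noise; a term
        # whose standardized contribution is numerically zero is removable.
        for t in eligible:
            if abs(fit.params[t]) * max(col_sd[t], 1.0) < 1e-6 * y_scale:
                pvals[t] = 1.0
        worst = pvals.idxmax()
        if pvals[worst] > alpha:
            current.remove(worst)
        else:
            return current


def seeded_folds(ids: Sequence, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Near-equal random partition of participant ids into k folds.

    Ids are sorted before shuffling so the partition does not depend on the
    row order of the input table.
    """
    ids = np.sort(np.asarray(ids))
    if k < 2 or k > len(ids):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={len(ids)}")
    perm = rng.permutation(len(ids))
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def _prepare(cohort: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, np.ndarray]:
    df = covariate_frame(cohort)
    y = df[f"awake_{outcome}_mean"].to_numpy(dtype=float) - \
        df[f"first_office_{outcome}"].to_numpy(dtype=float)
    return df, y


def kfold_majority_select(cohort: pd.DataFrame, outcome: str,
                          config: DevelopmentConfig) -> tuple[dict, dict, list[str]]:
    """Stage-1 CV: per-fold backward elimination and majority-vote selection.

    Returns ``(per_fold_selected, vote_counts, final_terms)`` where the final
    term list is the prespecified terms plus every candidate selected in at
    least ``majority_threshold`` of the folds.
    """
    outcome = outcome.lower()
    terms = config.candidate_terms or default_candidate_terms(outcome, config.include_race)
    presp = prespecified_names(outcome)
    df, y = _prepare(cohort, outcome)
    X = design_matrix(terms, df)
    names = [t.name for t in terms]
    folds = seeded_folds(df["id"].to_numpy(), config.k_folds,
                         substream(config.seed, f"kfold-select-{outcome}"))
    min_fold = min(len(f) for f in folds)
    if (len(df) - min_fold) <= len(names):
        raise ValueError("training folds smaller than the number of candidate terms")
    id_pos = pd.Series(np.arange(len(df)), index=df["id"].to_numpy())
    per_fold: dict[int, list[str]] = {}
    votes: dict[str, int] = {n: 0 for n in names}
    for i, heldout in enumerate(folds):
        train = np.setdiff1d(df["id"].to_numpy(), heldout)
        rows = id_pos[train].to_numpy()
        selected = backward_eliminate(X.iloc[rows], y[rows], names, presp,
                                      alpha=config.elimination_alpha, term_specs=terms,
                                      hierarchy_rule=config.hierarchy_rule)
        per_fold[i] = selected
        for t in selected:
            votes[t] += 1
    thr = config.threshold()
    final = [n for n in names if n in presp or votes[n] >= thr]
    return per_fold, votes, final


def internal_validate(cohort: pd.DataFrame, outcome: str, final_terms: Sequence[str],
                      k_folds: int = 10, seed: int = 0,
                      candidate_terms: Sequence[TermSpec] | None = None) -> pd.DataFrame:
    """Stage-2 CV: refit the fixed term set per fold, predict the held-out fold.

    Returns a table (id, fold, predicted, observed) with exactly one held-out
    predicted out-of-office BP per participant.
    """
    outcome = outcome.lower()
    terms = candidate_terms or default_candidate_terms(outcome, include_race=True)
    by_name = {t.name: t for t in terms}
    try:
        specs = [by_name[n] for n in final_terms]
    except KeyError as e:
        raise ValueError(f"unknown final term {e.args[0]!r}") from None
    df, y = _prepare(cohort, outcome)
    X = design_matrix(specs, df)
    first = df[f"first_office_{outcome}"].to_numpy(dtype=float)
    observed = df[f"awake_{outcome}_mean"].to_numpy(dtype=float)
    ids = df["id"].to_numpy()
    id_pos = pd.Series(np.arange(len(df)), index=ids)
    folds = seeded_folds(ids, k_folds, substream(seed, f"kfold-validate-{outcome}"))
    out = []
    for i, heldout in enumerate(folds):
        test_rows = id_pos[heldout].to_numpy()
        train_rows = id_pos[np.setdiff1d(ids, heldout)].to_numpy()
        fit = fit_least_squares(X.iloc[train_rows], y[train_rows])
        pred = first[test_rows] + X.iloc[test_rows].to_numpy() @ fit.params.to_numpy()
        out.append(pd.DataFrame({"id": ids[test_rows], "fold": i,
                                 "predicted": pred, "observed": observed[test_rows]}))
    table = pd.concat(out, ignore_index=True).sort_values("id", ignore_index=True)
    assert len(table) == len(df) and table["id"].is_unique
    return table


@dataclass
class DevelopmentResult:
    final_model: PredictionModel
    per_fold_selected: dict[int, list[str]]
    vote_counts: dict[str, int]
    heldout_predictions: pd.DataFrame


def develop_model(cohort: pd.DataFrame, outcome: str,
                  config: DevelopmentConfig | None = None) -> DevelopmentResult:
    """Full development: CV selection, full-data refit, internal validation."""
    config = config or DevelopmentConfig()
    outcome = outcome.lower()
    terms = config.candidate_terms or default_candidate_terms(outcome, config.include_race)
    per_fold, votes, final = kfold_majority_select(cohort, outcome, config)
    by_name = {t.name: t for t in terms}
    specs = [by_name[n] for n in final]
    df, y = _prepare(cohort, outcome)
    fit = fit_least_squares(design_matrix(specs, df), y)
    model = PredictionModel(
        outcome=outcome,
        terms=specs,
        coefficients={n: float(fit.params[n]) for n in final},
        provenance="proofbp_us",
        standard_errors={n: float(fit.bse[n]) for n in final},
    )
    heldout = internal_validate(cohort, outcome, final, config.k_folds, config.seed,
                                candidate_terms=terms)
    return DevelopmentResult(model, per_fold, votes, heldout)


class ProofBPUSEstimator(BaseEstimator):
    """sklearn-style wrapper around the development procedure.

    ``fit`` takes a cohort table (the response is derived internally from the
    awake mean and first office reading of ``outcome``); ``predict`` returns
    predicted out-of-office BP in mm Hg.

    Fitted attributes: ``model_``, ``vote_counts_``, ``per_fold_selected_``,
    ``heldout_predictions_``, ``final_terms_``.
    """

    def __init__(self, outcome: str = "sbp", k_folds: int = 10,
                 elimination_alpha: float = 0.05, majority_threshold: int | None = None,
                 hierarchy_rule: bool = True, include_race: bool = False,
                 candidate_terms: list[TermSpec] | None = None, random_state: int = 0):
        self.outcome = outcome
        self.k_folds = k_folds
        self.elimination_alpha = elimination_alpha
        self.majority_threshold = majority_threshold
        self.hierarchy_rule = hierarchy_rule
        self.include_race = include_race
        self.candidate_terms = candidate_terms
        self.random_state = random_state

    def _config(self) -> DevelopmentConfig:
        return DevelopmentConfig(
            k_folds=self.k_folds,
            elimination_alpha=self.elimination_alpha,
            majority_threshold=self.majority_threshold,
            hierarchy_rule=self.hierarchy_rule,
            include_race=self.include_race,
            seed=self.random_state,
            candidate_terms=self.candidate_terms,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "ProofBPUSEstimator":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a cohort DataFrame")
        result = develop_model(X, self.outcome, self._config())
        self.model_ = result.final_model
        self.per_fold_selected_ = result.per_fold_selected
        self.vote_counts_ = result.vote_counts
        self.heldout_predictions_ = result.heldout_predictions
        self.final_terms_ = [t.name for t in result.final_model.terms]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        return np.asarray(self.model_.predict_out_of_office(covariate_frame(X)))
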