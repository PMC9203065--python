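"""Synthetic pooled-cohort and survey generators with known ground truth.

The generator emulates the structure of a pooled US ambulatory-BP cohort:
covariate marginals (age, sex, BMI, comorbidities, smoking, medication use),
two-plus office readings per visit with a small within-visit drift, and a mean
awake (out-of-office) BP produced by a *known* linear model on covariates —

    awake_mean = first_office + beta . x + Normal(0, noise_sd)

so every downstream stage (model development, validation, triage, projection)
can be tested against the truth that generated the data.  The survey generator
produces the deployment population: office readings and covariates only, no
awake data, plus sampling weights and stratum/PSU design labels.

Awake readings are scattered around the awake mean with their sample mean
pinned to it exactly, so reading-level and mean-level pipelines agree and the
zero-noise limit is exact.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .model import design_matrix, resolve_term, ModelSchemaError

__all__ = [
    "CohortConfig",
    "ConfigurationError",
    "DEFAULT_MARGINALS",
    "DEFAULT_TRUE_BETA_SBP",
    "DEFAULT_TRUE_BETA_DBP",
    "generate_cohort",
    "generate_survey",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_ground_truth",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


#: Default covariate marginals (pooled-cohort scale): mean/SD for continuous
#: covariates, proportions for binaries, category shares for smoking.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age": {"mean": 52.0, "sd": 11.9, "min": 20.0, "max": 90.0},
    "male": {"p": 0.38},
    "race_black": {"p": 0.54},
    "bmi": {"mean": 29.8, "sd": 6.5, "min": 15.0, "max": 60.0},
    "diabetes": {"p": 0.157},
    "ckd": {"p": 0.10},
    "cvd_history": {"p": 0.056},
    "self_reported_htn": {"p": 0.35},
    "hs_degree": {"p": 0.897},
    "alcohol_any": {"p": 0.667},
    "smoking": {"p_never": 0.66, "p_former": 0.233, "p_current": 0.107},
}

#: Covariate dependence of the latent first office reading, calibrated so the
#: default marginals reproduce a first-reading mean (SD) of about
#: 121.8 (16.5) mm Hg SBP and 75.3 (9.8) mm Hg DBP.
DEFAULT_OFFICE_MODEL: dict[str, dict[str, float]] = {
    "sbp": {"intercept": 87.15, "age": 0.35, "bmi": 0.50,
            "antihypertensive_use": 5.0, "resid_sd": 15.46},
    "dbp": {"intercept": 62.03, "age": 0.10, "bmi": 0.25,
            "antihypertensive_use": 2.0, "resid_sd": 9.55},
}

#: True awake-minus-first-office difference models.  Regression to the mean
#: (negative first-office coefficient) plus modest demographic effects; the
#: intercepts set the population mean difference to about +5.5/+3.2 mm Hg so
#: the awake means land near 127.3/78.5 mm Hg.
DEFAULT_TRUE_BETA_SBP: dict[str, float] = {
    "intercept": 39.7,
    "first_office_sbp": -0.35,
    "age": 0.05,
    "male": 1.5,
    "bmi": 0.2,
    "antihypertensive_use": -3.0,
    "diabetes": 1.5,
}
DEFAULT_TRUE_BETA_DBP: dict[str, float] = {
    "intercept": 20.5,
    "first_office_dbp": -0.3,
    "age": 0.02,
    "male": 1.0,
    "bmi": 0.15,
    "antihypertensive_use": -2.0,
}

SBP_WINDOW = (60.0, 260.0)  # plausibility clip, mm Hg
DBP_WINDOW = (30.0, 160.0)


@dataclass
class CohortConfig:
    """Everything the generators need; defaults emulate the pooled cohort."""

    n_participants: int = 3058
    seed: int = 0
    covariate_marginals: dict = field(default_factory=dict)  # overrides merged over defaults
    true_beta_sbp: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA_SBP))
    true_beta_dbp: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA_DBP))
    noise_sd_sbp: float = 8.0
    noise_sd_dbp: float = 6.0
    n_office_readings: int = 3
    office_reading_sd_sbp: float = 6.7
    office_reading_sd_dbp: float = 4.7
    office_drift_mean_sbp: float = -0.3
    office_drift_mean_dbp: float = -0.2
    n_awake_readings: int = 30
    awake_reading_sd_sbp: float = 12.0
    awake_reading_sd_dbp: float = 9.0
    prop_treated: float = 0.31
    office_model: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_OFFICE_MODEL))

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_office_readings < 2:
            raise ConfigurationError("n_office_readings must be >= 2")
        for name in ("noise_sd_sbp", "noise_sd_dbp", "office_reading_sd_sbp",
                     "office_reading_sd_dbp", "awake_reading_sd_sbp",
                     "awake_reading_sd_dbp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.prop_treated <= 1.0:
            raise ConfigurationError("prop_treated must be in [0, 1]")
        for attr in ("true_beta_sbp", "true_beta_dbp"):
            for term in getattr(self, attr):
                try:
                    resolve_term(term)
                except ModelSchemaError as e:
                    raise ConfigurationError(f"{attr}: {e}") from None

    def marginals(self) -> dict[str, dict[str, float]]:
        out = copy.deepcopy(DEFAULT_MARGINALS)
        for k, v in self.covariate_marginals.items():
            out.setdefault(k, {}).update(v)
        return out


def _draw_covariates(cfg: CohortConfig, n: int, rng: np.random.Generator,
                     min_age: float | None = None) -> pd.DataFrame:
    m = cfg.marginals()
    df = pd.DataFrame(index=range(n))
    for cov in ("age", "bmi"):
        p = m[cov]
        lo = p.get("min", -np.inf)
        if cov == "age" and min_age is not None:
            lo = max(lo, min_age)
        df[cov] = np.clip(rng.normal(p["mean"], p["sd"], n), lo, p.get("max", np.inf))
    for cov in ("male", "race_black", "diabetes", "ckd", "cvd_history",
                "self_reported_htn", "hs_degree", "alcohol_any"):
        df[cov] = (rng.random(n) < m[cov]["p"]).astype(int)
    df["antihypertensive_use"] = (rng.random(n) < cfg.prop_treated).astype(int)
    ps = m["smoking"]
    probs = np.array([ps["p_never"], ps["p_former"], ps["p_current"]])
    cats = rng.choice(np.array(["never", "former", "current"]), size=n, p=probs / probs.sum())
    df["smoking"] = cats
    df["smoking_former"] = (cats == "former").astype(int)
    df["smoking_current"] = (cats == "current").astype(int)
    return df


def _office_readings(cfg: CohortConfig, df: pd.DataFrame, rng: np.random.Generator) -> None:
    k = cfg.n_office_readings
    for bp, window in (("sbp", SBP_WINDOW), ("dbp", DBP_WINDOW)):
        om = cfg.office_model[bp]
        latent = (
            om["intercept"]
            + om.get("age", 0.0) * df["age"].to_numpy()
            + om.get("bmi", 0.0) * df["bmi"].to_numpy()
            + om.get("antihypertensive_use", 0.0) * df["antihypertensive_use"].to_numpy()
            + rng.normal(0.0, om["resid_sd"], len(df))
        )
        first = np.clip(latent, *window)
        df[f"office_{bp}_1"] = first
        drift = getattr(cfg, f"office_drift_mean_{bp}")
        sd = getattr(cfg, f"office_reading_sd_{bp}")
        for j in range(2, k + 1):
            val = first + drift * (j - 1) / (k - 1) + rng.normal(0.0, sd, len(df))
            df[f"office_{bp}_{j}"] = np.clip(val, *window)
        df[f"first_office_{bp}"] = df[f"office_{bp}_1"]


def _awake(cfg: CohortConfig, df: pd.DataFrame, rng_noise: np.random.Generator,
           rng_read: np.random.Generator) -> None:
    for bp, window in (("sbp", SBP_WINDOW), ("dbp", DBP_WINDOW)):
        beta = getattr(cfg, f"true_beta_{bp}")
        terms = [resolve_term(t) for t in beta]
        X = design_matrix(terms, df)
        diff = X.to_numpy() @ np.array([beta[t.name] for t in terms])
        noise = rng_noise.normal(0.0, getattr(cfg, f"noise_sd_{bp}"), len(df))
        mean = np.clip(df[f"office_{bp}_1"].to_numpy() + diff + noise, *window)
        m = cfg.n_awake_readings
        if m >= 1:
            eps = rng_read.normal(0.0, getattr(cfg, f"awake_reading_sd_{bp}"), (len(df), m))
            eps -= eps.mean(axis=1, keepdims=True)  # pin sample mean to the true mean
            readings = mean[:, None] + eps
            # keep readings inside the plausibility window without moving the
            # row mean: redistribute any clip deficit over the other readings
            for _ in range(100):
                readings = np.clip(readings, *window)
                err = mean - readings.mean(axis=1)
                if np.abs(err).max() < 1e-12:
                    break
                readings += err[:, None]
            mean = readings.mean(axis=1)
            df[f"awake_{bp}_readings"] = [
                ";".join(f"{v:.6g}" for v in row) for row in readings
            ]
        else:
            df[f"awake_{bp}_readings"] = ""
        df[f"awake_{bp}_mean"] = mean


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a pooled-cohort table plus the ground truth that produced it.

    Returns ``(cohort, truth)`` where ``truth`` records the true difference
    models, noise SDs and seed, for use as an oracle in tests.
    Deterministic for a fixed ``config.seed``.
    """
    n = config.n_participants
    df = _draw_covariates(config, n, substream(config.seed, "covariates"))
    _office_readings(config, df, substream(config.seed, "office"))
    _awake(config, df, substream(config.seed, "awake-noise"),
           substream(config.seed, "awake-readings"))
    df.insert(0, "id", [f"p{i + 1:05d}" for i in range(n)])
    truth = {
        "seed": config.seed,
        "true_beta_sbp": dict(config.true_beta_sbp),
        "true_beta_dbp": dict(config.true_beta_dbp),
        "noise_sd_sbp": config.noise_sd_sbp,
        "noise_sd_dbp": config.noise_sd_dbp,
    }
    return df, truth


def generate_survey(config: CohortConfig, n: int,
                    weight_scheme: str | Mapping[Any, float] = "uniform",
                    n_psu_per_stratum: int = 10) -> pd.DataFrame:
    """Generate a survey sample: covariates + office readings, no awake data.

    ``weight_scheme`` is either ``"uniform"`` (all weights 1, single stratum)
    or a mapping ``{stratum_label: weight}``; persons are allocated to strata
    uniformly at random and inherit the stratum weight.  All ages are >= 20
    and every person has >= 2 office readings.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = substream(config.seed, "survey")
    df = _draw_covariates(config, n, rng, min_age=20.0)
    _office_readings(config, df, substream(config.seed, "survey-office"))
    if weight_scheme == "uniform":
        strata, weights = np.zeros(n, dtype=int), np.ones(n)
    else:
        labels = list(weight_scheme)
        idx = rng.integers(0, len(labels), n)
        strata = np.array([labels[i] for i in idx])
        weights = np.array([float(weight_scheme[labels[i]]) for i in idx])
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ConfigurationError("survey weights must be >= 0 with positive total")
    df.insert(0, "id", [f"s{i + 1:05d}" for i in range(n)])
    df["stratum"] = strata
    df["psu"] = rng.integers(1, n_psu_per_stratum + 1, n)
    df["weight"] = weights
    return df


# -- plain-text IO ----------------------------------------------------------

def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def awake_readings_list(df: pd.DataFrame, bp: str) -> list[np.ndarray]:
    """Parse the semicolon-packed awake reading column into float arrays."""
    col = df[f"awake_{bp}_readings"]
    return [
        np.array([float(x) for x in s.split(";")]) if isinstance(s, str) and s else np.array([])
        for s in col
    ]
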