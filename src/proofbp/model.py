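"""Linear difference models for out-of-office blood pressure.

A model predicts the difference between a patient's mean awake (out-of-office)
BP and the first office reading, as a linear combination of covariate terms
(main effects, squares, pairwise products).  Predicted out-of-office BP is the
first office reading plus that predicted difference.

Coefficients are never hard-coded: a :class:`PredictionModel` is either fitted
from data (see :mod:`proofbp.development`) or loaded from a JSON file supplied
by the user (e.g. transcribed published coefficients).

Units: BP in mm Hg, age in years, BMI in kg/m^2; binary covariates coded 0/1
with sex coded male=1, female=0.  Coefficients are on natural scales — no
internal standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "TermSpec",
    "PredictionModel",
    "ModelSchemaError",
    "MissingCovariateError",
    "term_value",
    "term_column",
    "design_matrix",
    "resolve_term",
    "covariate_frame",
    "load_model",
    "save_model",
]

#: Covariates a cohort table is expected to carry (after `covariate_frame`).
COVARIATES = (
    "age",
    "male",
    "race_black",
    "bmi",
    "diabetes",
    "ckd",
    "cvd_history",
    "self_reported_htn",
    "antihypertensive_use",
    "hs_degree",
    "alcohol_any",
    "smoking_former",
    "smoking_current",
    "first_office_sbp",
    "first_office_dbp",
)

_TRANSFORMS = ("identity", "square", "product")


class ModelSchemaError(ValueError):
    """A model definition violates the model schema."""


class MissingCovariateError(KeyError):
    """A record lacks a covariate a term needs (complete-case requirement)."""


@dataclass(frozen=True)
class TermSpec:
    """One term of a linear difference model.

    ``identity`` terms have one base covariate (zero for the intercept),
    ``square`` exactly one, ``product`` exactly two.  ``centering`` offsets
    are subtracted from each base covariate before the transform.
    """

    name: str
    base_covariates: tuple[str, ...] = ()
    transform: str = "identity"
    centering: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_covariates", tuple(self.base_covariates))
        object.__setattr__(self, "centering", tuple(float(c) for c in self.centering))
        if self.transform not in _TRANSFORMS:
            raise ModelSchemaError(
                f"term {self.name!r}: unknown transform {self.transform!r} "
                f"(expected one of {_TRANSFORMS})"
            )
        n = len(self.base_covariates)
        if self.transform == "identity" and n > 1:
            raise ModelSchemaError(f"term {self.name!r}: identity terms take at most 1 covariate")
        if self.transform == "square" and n != 1:
            raise ModelSchemaError(f"term {self.name!r}: square terms take exactly 1 covariate")
        if self.transform == "product" and n != 2:
            raise ModelSchemaError(f"term {self.name!r}: product terms take exactly 2 covariates")
        if self.centering and len(self.centering) != n:
            raise ModelSchemaError(f"term {self.name!r}: centering length must match covariates")

    @property
    def is_intercept(self) -> bool:
        return not self.base_covariates

    def _offsets(self) -> tuple[float, ...]:
        return self.centering or tuple(0.0 for _ in self.base_covariates)


def _base_values(term: TermSpec, getter, who: str) -> list[float]:
    vals = []
    for cov, off in zip(term.base_covariates, term._offsets()):
        try:
            v = getter(cov)
        except KeyError:
            raise MissingCovariateError(
                f"covariate {cov!r} required by term {term.name!r} is missing for {who}"
            ) from None
        vals.append(np.asarray(v, dtype=float) - off)
    return vals


def _combine(term: TermSpec, vals: Sequence[Any]):
    if term.is_intercept:
        return 1.0
    if term.transform == "identity":
        return vals[0]
    if term.transform == "square":
        return vals[0] ** 2
    return vals[0] * vals[1]


def term_value(term: TermSpec, record: Mapping[str, Any]) -> float:
    """Value of one term for a single participant record (a mapping)."""
    who = f"participant {record.get('id', '<unknown>')!r}" if hasattr(record, "get") else "record"
    vals = _base_values(term, record.__getitem__, who)
    out = _combine(term, vals)
    return float(out)


def term_column(term: TermSpec, df: pd.DataFrame) -> np.ndarray:
    """Vectorized term values over a cohort table."""
    if term.is_intercept:
        return np.ones(len(df))
    vals = _base_values(term, lambda c: df[c].to_numpy(dtype=float), "cohort table")
    for cov, v in zip(term.base_covariates, vals):
        bad = np.isnan(v)
        if bad.any():
            ids = df.index[bad][:5].tolist()
            raise MissingCovariateError(
                f"covariate {cov!r} has {int(bad.sum())} missing values "
                f"(complete cases required; first rows {ids})"
            )
    return np.asarray(_combine(term, vals), dtype=float)


def design_matrix(terms: Sequence[TermSpec], df: pd.DataFrame) -> pd.DataFrame:
    """Design matrix with one column per term, indexed like ``df``."""
    names = [t.name for t in terms]
    if len(set(names)) != len(names):
        raise ModelSchemaError(f"duplicate term names: {sorted(names)}")
    return pd.DataFrame({t.name: term_column(t, df) for t in terms}, index=df.index)


def covariate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Return ``df`` augmented with derived modelling columns.

    Adds ``first_office_sbp``/``first_office_dbp`` (first office reading) and
    0/1 smoking indicators when only the raw columns are present.
    """
    out = df.copy()
    for bp in ("sbp", "dbp"):
        col = f"first_office_{bp}"
        if col not in out.columns and f"office_{bp}_1" in out.columns:
            out[col] = out[f"office_{bp}_1"].astype(float)
    if "smoking" in out.columns:
        if "smoking_former" not in out.columns:
            out["smoking_former"] = (out["smoking"] == "former").astype(int)
        if "smoking_current" not in out.columns:
            out["smoking_current"] = (out["smoking"] == "current").astype(int)
    return out


def resolve_term(name: str, known: Iterable[str] = COVARIATES) -> TermSpec:
    """Build a TermSpec from a conventional term name.

    ``intercept``; a covariate name (main effect); ``<cov>_sq`` (square);
    ``<a>_x_<b>`` (product).  Unknown names raise ``ModelSchemaError``.
    """
    known = set(known)
    if name == "intercept":
        return TermSpec("intercept")
    if name in known:
        return TermSpec(name, (name,), "identity")
    if name.endswith("_sq") and name[:-3] in known:
        return TermSpec(name, (name[:-3],), "square")
    if "_x_" in name:
        for i in range(len(name)):
            if name[i : i + 3] == "_x_":
                a, b = name[:i], name[i + 3 :]
                if a in known and b in known:
                    return TermSpec(name, (a, b), "product")
    raise ModelSchemaError(f"cannot resolve term name {name!r} to a known covariate or transform")


_OUTCOMES = ("sbp", "dbp")
_PROVENANCES = ("original_proofbp", "proofbp_us", "user")
PRESPECIFIED = ("intercept", "age", "male")  # plus first office reading of the outcome


def prespecified_names(outcome: str) -> list[str]:
    """Terms forced into every developed model: intercept, age, sex, first office reading."""
    return [*PRESPECIFIED, f"first_office_{outcome}"]


@dataclass
class PredictionModel:
    """A fitted or user-supplied difference model for one outcome (SBP or DBP)."""

    outcome: str
    terms: list[TermSpec]
    coefficients: dict[str, float]
    provenance: str = "user"
    version: str = "1"
    standard_errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outcome = self.outcome.lower()
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.outcome not in _OUTCOMES:
            problems.append(f"outcome must be one of {_OUTCOMES}, got {self.outcome!r}")
        if self.provenance not in _PROVENANCES:
            problems.append(f"provenance must be one of {_PROVENANCES}, got {self.provenance!r}")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            problems.append("duplicate term names")
        if "intercept" not in names:
            problems.append("missing required term 'intercept'")
        extra = set(self.coefficients) - set(names)
        missing = set(names) - set(self.coefficients)
        if extra:
            problems.append(f"coefficients for unknown terms: {sorted(extra)}")
        if missing:
            problems.append(f"terms without coefficients: {sorted(missing)}")
        # Developed models must carry the prespecified terms; ad-hoc user
        # models (e.g. intercept-only toys) are exempt.
        if self.provenance in ("original_proofbp", "proofbp_us") and self.outcome in _OUTCOMES:
            for req in prespecified_names(self.outcome):
                if req not in names:
                    problems.append(f"missing prespecified term {req!r}")
        if problems:
            raise ModelSchemaError("; ".join(problems))

    # -- prediction ---------------------------------------------------------

    def _first_office(self, data) -> Any:
        col = f"first_office_{self.outcome}"
        if isinstance(data, pd.DataFrame):
            if col not in data.columns:
                raise MissingCovariateError(f"column {col!r} not in table")
            return data[col].to_numpy(dtype=float)
        try:
            return float(data[col])
        except KeyError:
            raise MissingCovariateError(f"{col!r} missing from record") from None

    def predict_difference(self, data):
        """Predicted (awake minus first office) difference, in mm Hg."""
        if isinstance(data, pd.DataFrame):
            X = design_matrix(self.terms, data)
            beta = np.array([self.coefficients[t.name] for t in self.terms])
            return X.to_numpy() @ beta
        return float(
            sum(self.coefficients[t.name] * term_value(t, data) for t in self.terms)
        )

    def predict_out_of_office(self, data):
        """Predicted mean awake BP: first office reading + predicted difference."""
        return self._first_office(data) + self.predict_difference(data)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "terms": [
                {
                    "name": t.name,
                    "base_covariates": list(t.base_covariates),
                    "transform": t.transform,
                    "centering": list(t.centering),
                }
                for t in self.terms
            ],
            "coefficients": dict(self.coefficients),
            "provenance": self.provenance,
            "version": self.version,
            "standard_errors": dict(self.standard_errors),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PredictionModel":
        required = {"outcome", "terms", "coefficients"}
        missing = required - set(d)
        if missing:
            raise ModelSchemaError(f"model file missing fields: {sorted(missing)}")
        terms = []
        for td in d["terms"]:
            if "name" not in td:
                raise ModelSchemaError("every term needs a 'name'")
            terms.append(
                TermSpec(
                    name=td["name"],
                    base_covariates=tuple(td.get("base_covariates", ())),
                    transform=td.get("transform", "identity"),
                    centering=tuple(td.get("centering", ())),
                )
            )
        return cls(
            outcome=str(d["outcome"]),
            terms=terms,
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            provenance=d.get("provenance", "user"),
            version=str(d.get("version", "1")),
            standard_errors={k: float(v) for k, v in d.get("standard_errors", {}).items()},
        )


def save_model(model: PredictionModel, path) -> None:
    model.validate()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> PredictionModel:
    with open(path, encoding="utf-8") as fh:
        return PredictionModel.from_dict(json.load(fh))
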