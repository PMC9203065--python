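"""End-to-end orchestration of the synthetic study.

``run_full_study`` sequences: simulate cohort -> classify -> develop the
SBP/DBP difference models -> internally validate -> optimize referral ranges
-> phenotype-by-recommendation table -> simulate survey and project.  Every
stage draws from a named substream of the single master seed, so re-running
with the same configuration reproduces every artifact byte for byte; the
manifest records files, SHA-256 hashes and the seeds consumed.

Emitted tables are UTF-8 TSV/CSV with headers; reports are JSON.  BP values
in artifacts are serialized at one-decimal precision while all internal
computation is full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import BPThresholds, classify_cohort
from .cohort import CohortConfig, generate_cohort, generate_survey, write_ground_truth
from .development import DevelopmentConfig, develop_model
from .metrics import accuracy_report
from .model import covariate_frame, save_model
from .projection import ModelStrategy, OfficeBandStrategy, project_strategies
from .triage import decide_many, optimize_ranges, phenotype_by_recommendation

__all__ = ["PipelineConfig", "run_full_study"]

log = logging.getLogger(__name__)

_BP_COL_HINTS = ("sbp", "dbp", "predicted", "observed", "threshold")


@dataclass
class PipelineConfig:
    """Study-level configuration; defaults mirror the full-scale analysis."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    development: DevelopmentConfig = field(default_factory=DevelopmentConfig)
    thresholds: BPThresholds = field(default_factory=BPThresholds)
    sbp_grid: tuple[float, float, float] = (120.0, 150.0, 5.0)
    dbp_grid: tuple[float, float, float] = (70.0, 100.0, 5.0)
    misclassification_limit: float = 0.20
    n_boot: int = 500
    survey_n: int = 10974
    survey_weight_scheme: str | dict = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.misclassification_limit < 1.0:
            raise ValueError("misclassification_limit must be in (0, 1)")
        # master seed fans out to the stage configs
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.development = dataclasses.replace(self.development, seed=self.seed)


def _round_bp(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f" and any(h in c for h in _BP_COL_HINTS):
            out[c] = out[c].round(1)
    return out


def _write_table(df: pd.DataFrame, path: Path, sep: str = "\t") -> None:
    _round_bp(df).to_csv(path, sep=sep, index=False, float_format="%.6g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_study(config: PipelineConfig, out_dir) -> dict:
    """Run the whole synthetic study; return (and write) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        log.info("wrote %s", path)
        return path

    # 1. simulate
    cohort, truth = generate_cohort(config.cohort)
    emit("cohort.csv", lambda p: _round_bp(cohort).to_csv(p, index=False, float_format="%.6g"))
    emit("ground_truth.json", lambda p: write_ground_truth(truth, p))

    # 2. classify
    classified = classify_cohort(cohort, config.thresholds)
    emit("classification.tsv", lambda p: _write_table(classified, p))

    # 3. develop both outcomes
    results = {}
    for outcome in ("sbp", "dbp"):
        res = develop_model(cohort, outcome, config.development)
        results[outcome] = res
        emit(f"model_{outcome}.json", lambda p, m=res.final_model: save_model(m, p))
    dev_report = {
        outcome: {
            "final_terms": [t.name for t in res.final_model.terms],
            "vote_counts": res.vote_counts,
            "per_fold_selected": {str(k): v for k, v in res.per_fold_selected.items()},
        }
        for outcome, res in results.items()
    }
    emit("dev_report.json", lambda p: _write_json(dev_report, p))

    # 4. validate (internal CV held-out predictions)
    report = {}
    for outcome, res in results.items():
        ho = res.heldout_predictions
        acc = accuracy_report(
            ho["id"], ho["predicted"], ho["observed"],
            htn_threshold=getattr(config.thresholds, f"awake_{outcome}"),
            n_boot=config.n_boot, seed=config.seed,
        )
        report[outcome] = acc["metrics"]
        emit(f"residuals_{outcome}.tsv", lambda p, t=acc["residual_table"]: _write_table(t, p))
        emit(f"sens_spec_{outcome}.tsv", lambda p, t=acc["sens_spec_curve"]: _write_table(t, p))
        emit(f"heldout_{outcome}.tsv", lambda p, t=ho: _write_table(t, p))
    emit("report.json", lambda p: _write_json(report, p))

    # 5. optimize referral ranges on full-data model predictions
    cf = covariate_frame(cohort)
    predictions = pd.DataFrame({
        "id": cohort["id"],
        "pred_sbp": results["sbp"].final_model.predict_out_of_office(cf),
        "pred_dbp": results["dbp"].final_model.predict_out_of_office(cf),
    })
    observed = classified[["id", "awake_sbp", "awake_dbp"]]
    best, grid = optimize_ranges(predictions, observed, config.thresholds,
                                 config.sbp_grid, config.dbp_grid,
                                 config.misclassification_limit)
    emit("grid.tsv", lambda p: _write_table(grid, p))
    emit("best.json", lambda p: _write_json({
        "ranges": dataclasses.asdict(best.ranges),
        "display": best.ranges.display,
        "prop_referred": best.prop_referred,
        "prop_misclassified_among_not_referred": best.prop_misclassified_among_not_referred,
        "feasible": best.feasible,
        "decision_counts": best.decision_counts,
    }, p))

    # 6. phenotype-by-recommendation table
    decisions = pd.DataFrame({
        "id": predictions["id"],
        "decision": decide_many(predictions["pred_sbp"], predictions["pred_dbp"],
                                best.ranges),
    })
    table2 = phenotype_by_recommendation(classified, decisions,
                                         n_boot=config.n_boot, seed=config.seed)
    emit("table2.tsv", lambda p: _write_table(table2, p))

    # 7. survey projection
    survey = generate_survey(config.cohort, config.survey_n, config.survey_weight_scheme)
    strategies = {
        "proofbp_us": ModelStrategy(results["sbp"].final_model,
                                    results["dbp"].final_model, best.ranges),
        "acc_aha": OfficeBandStrategy(),
    }
    proj = project_strategies(survey, strategies, config.thresholds,
                              n_boot=min(config.n_boot, 200), seed=config.seed)
    emit("projection.json", lambda p: _write_json({
        "total_population": proj.total_population,
        "n_excluded": proj.n_excluded,
        "table": proj.table,
    }, p))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_participants": config.cohort.n_participants,
        "files": {p.name: _sha256(p) for p in artifacts},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
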