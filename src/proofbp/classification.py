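"""Office / out-of-office BP computation and phenotype cross-classification.

Office BP is the mean of at least two office readings; out-of-office BP is
the mean awake ambulatory BP, requiring at least ten awake readings for a
complete recording.  Hypertension uses the 130/80 mm Hg thresholds with the
OR rule (SBP >= 130 or DBP >= 80), closed lower bound, no pre-rounding.

Crossing office and out-of-office status gives four phenotypes; whether the
participant takes antihypertensive medication changes only the display name
(e.g. masked hypertension vs masked uncontrolled hypertension).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BPThresholds",
    "Phenotype",
    "InsufficientReadingsError",
    "mean_office_bp",
    "awake_mean",
    "is_hypertensive",
    "classify_phenotype",
    "phenotype_display",
    "classify_cohort",
]


class InsufficientReadingsError(ValueError):
    """Participant fails a minimum-reading inclusion criterion."""


@dataclass(frozen=True)
class BPThresholds:
    office_sbp: float = 130.0
    office_dbp: float = 80.0
    awake_sbp: float = 130.0
    awake_dbp: float = 80.0
    min_awake_readings: int = 10
    min_office_readings: int = 2

    def __post_init__(self) -> None:
        for f in ("office_sbp", "office_dbp", "awake_sbp", "awake_dbp"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.min_awake_readings < 1 or self.min_office_readings < 1:
            raise ValueError("minimum reading counts must be >= 1")


class Phenotype(str, Enum):
    SUSTAINED_NORMOTENSION = "sustained_normotension"
    MASKED_HYPERTENSION = "masked_hypertension"
    WHITE_COAT_HYPERTENSION = "white_coat_hypertension"
    SUSTAINED_HYPERTENSION = "sustained_hypertension"


_DISPLAY = {
    (Phenotype.SUSTAINED_NORMOTENSION, False): "sustained normotension",
    (Phenotype.SUSTAINED_NORMOTENSION, True): "sustained controlled BP",
    (Phenotype.MASKED_HYPERTENSION, False): "masked hypertension",
    (Phenotype.MASKED_HYPERTENSION, True): "masked uncontrolled hypertension",
    (Phenotype.WHITE_COAT_HYPERTENSION, False): "white coat hypertension",
    (Phenotype.WHITE_COAT_HYPERTENSION, True): "white coat effect",
    (Phenotype.SUSTAINED_HYPERTENSION, False): "sustained hypertension",
    (Phenotype.SUSTAINED_HYPERTENSION, True): "sustained uncontrolled BP",
}


def phenotype_display(phenotype: Phenotype, treated: bool) -> str:
    """Clinical display name; the treated flag selects the variant only."""
    return _DISPLAY[(Phenotype(phenotype), bool(treated))]


def mean_office_bp(readings: Sequence[float], min_count: int = 2,
                   participant_id: str | None = None) -> float:
    """Arithmetic mean of the visit's office readings (>= min_count required)."""
    readings = np.asarray(readings, dtype=float)
    if len(readings) < min_count:
        who = f" for participant {participant_id}" if participant_id else ""
        raise InsufficientReadingsError(
            f"insufficient office readings{who}: {len(readings)} < {min_count}"
        )
    return float(readings.mean())


def awake_mean(readings: Sequence[float], min_count: int = 10,
               participant_id: str | None = None) -> float:
    """Mean awake BP; fewer than ``min_count`` readings is an exclusion."""
    readings = np.asarray(readings, dtype=float)
    if len(readings) < min_count:
        who = f" for participant {participant_id}" if participant_id else ""
        raise InsufficientReadingsError(
            f"incomplete awake recording{who}: {len(readings)} < {min_count} readings"
        )
    return float(readings.mean())


def is_hypertensive(sbp, dbp, sbp_thr: float = 130.0, dbp_thr: float = 80.0):
    """OR rule with closed lower bounds: SBP >= sbp_thr or DBP >= dbp_thr.

    Accepts scalars or arrays.
    """
    out = (np.asarray(sbp, dtype=float) >= sbp_thr) | (np.asarray(dbp, dtype=float) >= dbp_thr)
    return bool(out) if np.isscalar(sbp) or np.ndim(out) == 0 else out


def classify_phenotype(office_sbp: float, office_dbp: float, awake_sbp: float,
                       awake_dbp: float, treated: bool = False,
                       thresholds: BPThresholds = BPThresholds()) -> Phenotype:
    """Cross-classify office and out-of-office hypertension status."""
    office = is_hypertensive(office_sbp, office_dbp, thresholds.office_sbp, thresholds.office_dbp)
    ooo = is_hypertensive(awake_sbp, awake_dbp, thresholds.awake_sbp, thresholds.awake_dbp)
    if office and ooo:
        return Phenotype.SUSTAINED_HYPERTENSION
    if office:
        return Phenotype.WHITE_COAT_HYPERTENSION
    if ooo:
        return Phenotype.MASKED_HYPERTENSION
    return Phenotype.SUSTAINED_NORMOTENSION


def classify_cohort(cohort: pd.DataFrame,
                    thresholds: BPThresholds = BPThresholds()) -> pd.DataFrame:
    """Per-participant classification table for a cohort.

    Expects office reading columns ``office_sbp_1..k``/``office_dbp_1..k`` and
    awake means ``awake_sbp_mean``/``awake_dbp_mean``.  Returns a table with
    id, mean office BP, awake BP, hypertension flags, phenotype and treated.
    """
    sbp_cols = sorted(
        (c for c in cohort.columns if c.startswith("office_sbp_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    dbp_cols = sorted(
        (c for c in cohort.columns if c.startswith("office_dbp_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if len(sbp_cols) < thresholds.min_office_readings:
        raise InsufficientReadingsError(
            f"cohort has {len(sbp_cols)} office readings; "
            f">= {thresholds.min_office_readings} required"
        )
    mean_sbp = cohort[sbp_cols].mean(axis=1).to_numpy()
    mean_dbp = cohort[dbp_cols].mean(axis=1).to_numpy()
    awake_sbp = cohort["awake_sbp_mean"].to_numpy(dtype=float)
    awake_dbp = cohort["awake_dbp_mean"].to_numpy(dtype=float)
    office_htn = is_hypertensive(mean_sbp, mean_dbp, thresholds.office_sbp, thresholds.office_dbp)
    ooo_htn = is_hypertensive(awake_sbp, awake_dbp, thresholds.awake_sbp, thresholds.awake_dbp)
    phen = np.where(
        office_htn & ooo_htn, Phenotype.SUSTAINED_HYPERTENSION.value,
        np.where(office_htn, Phenotype.WHITE_COAT_HYPERTENSION.value,
                 np.where(ooo_htn, Phenotype.MASKED_HYPERTENSION.value,
                          Phenotype.SUSTAINED_NORMOTENSION.value)),
    )
    treated = cohort["antihypertensive_use"].astype(int).to_numpy()
    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "mean_office_sbp": mean_sbp,
            "mean_office_dbp": mean_dbp,
            "awake_sbp": awake_sbp,
            "awake_dbp": awake_dbp,
            "office_htn": office_htn.astype(int),
            "ooo_htn": ooo_htn.astype(int),
            "phenotype": phen,
            "treated": treated,
        }
    )
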