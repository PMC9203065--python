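"""Accuracy and discrimination metrics with BCa bootstrap intervals.

Accuracy of predicted vs observed out-of-office BP is summarized by the mean
difference (predicted minus observed), mean absolute difference and Pearson
correlation; discrimination of out-of-office hypertension by the AUROC
computed as pairwise concordance (ties counted one half, i.e. the
Mann-Whitney statistic via midranks).  Confidence intervals use the
bias-corrected and accelerated (BCa) bootstrap: bias correction z0 from the
share of bootstrap replicates below the point estimate, acceleration from
jackknife skewness, adjusted percentile endpoints.  Resampling is by
participant (row), never by reading.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mean_difference",
    "mean_absolute_difference",
    "pearson_r",
    "auroc",
    "sens_spec_at",
    "sens_spec_curve",
    "bca_interval",
    "subgroup_bias",
    "accuracy_report",
]


def _paired(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return p, o


def mean_difference(predicted, observed) -> float:
    """Mean of (predicted - observed), mm Hg."""
    p, o = _paired(predicted, observed)
    return float(np.mean(p - o))


def mean_absolute_difference(predicted, observed) -> float:
    p, o = _paired(predicted, observed)
    return float(np.mean(np.abs(p - o)))


def pearson_r(predicted, observed) -> float:
    p, o = _paired(predicted, observed)
    return float(stats.pearsonr(p, o).statistic)


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels lengths differ")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(s)  # midranks handle ties as 1/2
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sens_spec_at(predicted, observed_htn, threshold: float) -> tuple[float, float]:
    """Sensitivity/specificity of 'predicted >= threshold' for observed status."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed_htn).astype(bool)
    if not y.any() or y.all():
        raise ValueError("sensitivity/specificity undefined: both classes must be present")
    test_pos = p >= threshold
    sens = float(np.mean(test_pos[y]))
    spec = float(np.mean(~test_pos[~y]))
    return sens, spec


def sens_spec_curve(predicted, observed_htn, step: float = 1.0) -> pd.DataFrame:
    """Sensitivity/specificity at thresholds stepped over the prediction range."""
    p = np.asarray(predicted, dtype=float)
    thresholds = np.arange(np.floor(p.min()), np.ceil(p.max()) + step, step)
    rows = [(t, *sens_spec_at(p, observed_htn, t)) for t in thresholds]
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


# -- BCa bootstrap ----------------------------------------------------------

def _take(data, idx):
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    return np.asarray(data)[idx]


def _bca_endpoints(replicates: np.ndarray, z0: float, a: float,
                   level: float) -> tuple[float, float]:
    """Adjusted-percentile endpoints; z0 = a = 0 recovers the plain percentile
    interval from the same replicates."""
    alpha = (1.0 - level) / 2.0
    ends = []
    for q in (alpha, 1.0 - alpha):
        z = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        ends.append(float(np.quantile(replicates, adj)))
    return ends[0], ends[1]


def bca_interval(data, statistic: Callable, n_boot: int = 500, level: float = 0.95,
                 seed: int | np.random.Generator | None = None) -> tuple[float, float]:
    """BCa confidence interval for ``statistic(data)``.

    ``data`` is a DataFrame or array resampled by row; ``statistic`` maps a
    resampled table to a scalar.  Degenerate statistics (all replicates
    identical) return a zero-width interval with a warning.
    """
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = float(statistic(data))
    if not np.isfinite(point):
        raise ValueError("statistic not finite on the data")
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = statistic(_take(data, rng.integers(0, n, n)))
    if np.ptp(reps) == 0.0 and reps[0] == point:
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
        return point, point
    prop = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / n_boot
    prop = min(max(prop, 0.5 / n_boot), 1.0 - 0.5 / n_boot)
    z0 = float(stats.norm.ppf(prop))
    jack = np.empty(n)
    keep = np.arange(n)
    for i in range(n):
        jack[i] = statistic(_take(data, np.delete(keep, i)))
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0
    return _bca_endpoints(reps, z0, a, level)


def subgroup_bias(predicted, observed, groups, n_boot: int = 500, level: float = 0.95,
                  seed: int | None = None) -> pd.DataFrame:
    """Per-subgroup mean (predicted - observed) with BCa intervals."""
    p, o = _paired(predicted, observed)
    g = np.asarray(groups)
    if g.shape != p.shape:
        raise ValueError("groups length mismatch")
    rng = np.random.default_rng(seed)
    rows = []
    for label in pd.unique(g):
        mask = g == label
        resid = (p - o)[mask]
        if resid.size == 0:
            warnings.warn(f"empty subgroup {label!r} dropped")
            continue
        lo, hi = bca_interval(resid, np.mean, n_boot=n_boot, level=level, seed=rng)
        rows.append((label, float(resid.mean()), lo, hi, int(resid.size)))
    return pd.DataFrame(rows, columns=["group", "mean_difference", "ci_low", "ci_high", "n"])


def accuracy_report(ids, predicted, observed, htn_threshold: float,
                    n_boot: int = 500, level: float = 0.95,
                    seed: int | None = None) -> dict:
    """Full accuracy/discrimination summary for one outcome.

    ``htn_threshold`` defines observed out-of-office hypertension (>=).
    Returns point estimates with BCa CIs, the residual table and the
    sensitivity/specificity curve (1 mm Hg steps).
    """
    p, o = _paired(predicted, observed)
    rng = np.random.default_rng(seed)
    pairs = np.column_stack([p, o])
    labels = o >= htn_threshold

    def ci(stat):
        return bca_interval(pairs, stat, n_boot=n_boot, level=level, seed=rng)

    report = {
        "n": int(p.size),
        "mean_difference": {
            "estimate": mean_difference(p, o),
            "ci": ci(lambda t: np.mean(t[:, 0] - t[:, 1])),
        },
        "mean_absolute_difference": {
            "estimate": mean_absolute_difference(p, o),
            "ci": ci(lambda t: np.mean(np.abs(t[:, 0] - t[:, 1]))),
        },
        "pearson_r": {
            "estimate": pearson_r(p, o),
            "ci": ci(lambda t: stats.pearsonr(t[:, 0], t[:, 1]).statistic),
        },
        "auroc": {
            "estimate": auroc(p, labels),
            "ci": ci(lambda t: auroc(t[:, 0], t[:, 1] >= htn_threshold)),
        },
    }
    residuals = pd.DataFrame(
        {"id": np.asarray(ids), "predicted": p, "observed": o, "residual": p - o}
    )
    curve = sens_spec_curve(p, labels)
    return {"metrics": report, "residual_table": residuals, "sens_spec_curve": curve}
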