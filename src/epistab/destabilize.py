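"""Destabilization threshold calibration, binarization and recurrence.

A locus is *destabilized* (perturbed) in a sample when its β-value crosses a
threshold calibrated from healthy control cohorts: per control cohort the
mean β of each stable locus is computed, all cohort × locus means are pooled,
and the threshold is the 99.9th percentile of that pool (for the low,
normally unmethylated pole; the mirrored 0.1st percentile serves the high
pole). Binarized calls then give each locus a *recurrence* — the fraction of
cohort samples in which it is perturbed — with <5% termed low-recurrence
(likely patient-specific, clone-borne events) and ≥5% recurrent.

Percentiles use linear interpolation between order statistics (the common
"type 7" rule); this matters for the extreme 99.9th percentile of a finite
pool and is therefore fixed and recorded here.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix

__all__ = [
    "calibrate_threshold",
    "binarize",
    "recurrence",
    "conditional_mean_beta",
    "recurrence_beta_correlation",
    "RECURRENT_MIN",
]

#: Recurrence at or above this fraction classifies a locus as recurrent.
RECURRENT_MIN = 0.05


def calibrate_threshold(
    control_cohorts: Sequence[BetaMatrix],
    percentile: float = 99.9,
    pole: str = "low",
) -> float:
    """Destabilization threshold from pooled per-cohort locus means.

    Each input matrix must already be restricted to one ESL class. For the
    low pole the threshold is the ``percentile``-th percentile of the pooled
    means; for the high pole the mirrored ``100 − percentile``-th.
    """
    if len(control_cohorts) == 0:
        raise ValueError("at least one control cohort is required")
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if pole not in ("low", "high"):
        raise ValueError(f"pole must be 'low' or 'high', got {pole!r}")
    pooled = np.concatenate(
        [m.values.mean(axis=1).dropna().to_numpy() for m in control_cohorts]
    )
    if pooled.size == 0:
        raise ValueError("pooled per-locus means are empty")
    q = percentile if pole == "low" else 100.0 - percentile
    return float(np.percentile(pooled, q, method="linear"))


def binarize(matrix: BetaMatrix, threshold: float, pole: str = "low") -> pd.DataFrame:
    """Binary perturbation calls: 1.0 perturbed, 0.0 not, NaN missing.

    Low pole: a call of 1 requires β strictly above the threshold ("exceeding"
    — ties are stable at 0). High pole: strictly below the high-pole
    threshold. A threshold on the wrong side of 0.5 for its pole almost
    certainly signals a pole/threshold mix-up and draws a warning.
    """
    if pole not in ("low", "high"):
        raise ValueError(f"pole must be 'low' or 'high', got {pole!r}")
    if (pole == "low" and threshold >= 0.5) or (pole == "high" and threshold <= 0.5):
        warnings.warn(
            f"threshold {threshold} looks mismatched to the {pole} pole",
            stacklevel=2,
        )
    vals = matrix.values
    calls = (vals > threshold) if pole == "low" else (vals < threshold)
    return calls.astype(float).where(vals.notna())


def recurrence(calls: pd.DataFrame, recurrent_min: float = RECURRENT_MIN) -> pd.DataFrame:
    """Per-locus recurrence fraction and low/recurrent class.

    Missing calls are excluded from numerator and denominator alike, so
    cohort-specific missingness cannot bias the fraction. Class boundary:
    recurrent iff recurrence ≥ ``recurrent_min`` ("5% or more").
    """
    if calls.shape[1] < 1:
        raise ValueError("recurrence requires at least one sample")
    n_obs = calls.notna().sum(axis=1)
    n_pert = (calls == 1.0).sum(axis=1)
    frac = n_pert / n_obs
    return pd.DataFrame(
        {
            "recurrence": frac,
            "n_perturbed": n_pert,
            "n_obs": n_obs,
            "recurrence_class": np.where(frac >= recurrent_min, "recurrent", "low"),
        },
        index=calls.index,
    )


def conditional_mean_beta(matrix: BetaMatrix, calls: pd.DataFrame) -> pd.Series:
    """Mean β per locus over perturbed samples only; NaN when none perturbed."""
    vals = matrix.values.loc[calls.index, calls.columns]
    masked = vals.where(calls == 1.0)
    return masked.mean(axis=1).rename("conditional_mean_beta")


def recurrence_beta_correlation(
    recurrence_frac: pd.Series, conditional_means: pd.Series
) -> tuple[float, float]:
    """Pearson r (with two-sided t-test p) of recurrence vs conditional mean β.

    A strong positive correlation indicates that loci perturbed in more
    patients also carry higher methylation in the affected patients, i.e.
    recurrent destabilization reflects larger perturbed-cell fractions.
    """
    pairs = pd.concat([recurrence_frac, conditional_means], axis=1).dropna()
    if len(pairs) < 3:
        raise ValueError("need at least 3 loci with defined conditional means")
    x, y = pairs.iloc[:, 0].to_numpy(), pairs.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in recurrence or conditional means")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
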