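"""The DNA methylation instability (DMI) statistic.

DMI summarizes per-sample disruption of the stable methylome in one number:
the standard deviation of the sample's β-values over a designated set of
stable loci (by default the recurrently perturbed subset, since most stable
loci remain untouched in any one sample and would only dilute the signal).
An entirely unperturbed sample has β hugging the low pole and a small DMI;
an expanded epi-clone lifts a subset of loci toward intermediate values and
inflates the spread.

The standard deviation uses the n−1 denominator; since DMI values are
compared across samples scored over the same locus set, the denominator is a
global scale factor, but it must be fixed for reproducibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix

__all__ = ["compute_dmi", "dmi_trajectory", "dmi_age_trend", "AgeTrendResult"]

_TIMEPOINT_ORDER = {"diagnosis": 0, "remission": 1, "relapse": 2, "followup": 3, "none": 4}


def compute_dmi(
    matrix: BetaMatrix,
    esl_subset: pd.Index,
    subset_label: str = "recurrent",
) -> pd.DataFrame:
    """Per-sample DMI over ``esl_subset``.

    Returns a table indexed by sample with columns ``dmi``, ``n_loci`` and
    ``subset``. Missing β are dropped per sample; a sample with fewer than
    two usable loci gets a missing DMI with a warning.
    """
    esl_subset = pd.Index(esl_subset)
    if len(esl_subset) == 0:
        raise ValueError("esl_subset is empty")
    sub = matrix.select_probes(esl_subset).values
    n_loci = sub.notna().sum(axis=0)
    dmi = sub.std(axis=0, ddof=1)
    too_few = n_loci < 2
    if too_few.any():
        warnings.warn(
            f"{int(too_few.sum())} sample(s) with <2 usable loci: DMI missing",
            stacklevel=2,
        )
        dmi[too_few] = np.nan
    return pd.DataFrame(
        {"dmi": dmi, "n_loci": n_loci, "subset": subset_label},
        index=pd.Index(sub.columns, name="sample_id"),
    )


def dmi_trajectory(dmi_scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-patient DMI trajectory across clinical timepoints.

    Joins DMI scores with sample metadata and orders rows by patient and
    canonical timepoint order (diagnosis → remission → relapse → follow-up).
    A clone VAF column is carried through when present, so instability can be
    read next to the genetic clone-size proxy. Duplicated (patient,
    timepoint) pairs are an error.
    """
    cols = ["patient_id", "timepoint"] + (
        ["clone_vaf"] if "clone_vaf" in meta.columns else []
    )
    table = meta[cols].join(dmi_scores["dmi"], how="inner")
    if table.duplicated(subset=["patient_id", "timepoint"]).any():
        dup = table[table.duplicated(subset=["patient_id", "timepoint"])].iloc[0]
        raise ValueError(
            f"duplicated timepoint {dup['timepoint']!r} for patient {dup['patient_id']!r}"
        )
    order = table["timepoint"].map(_TIMEPOINT_ORDER)
    table = table.assign(_order=order).sort_values(
        ["patient_id", "_order"], kind="stable"
    ).drop(columns="_order")
    return table.reset_index()


@dataclass
class AgeTrendResult:
    """DMI-vs-age summary: binned means with CIs and a fit on bin means."""

    bins: pd.DataFrame
    slope: float
    intercept: float
    r_value: float
    p_value: float


def dmi_age_trend(
    dmi: pd.Series, ages: pd.Series, bin_width_years: float = 5.0
) -> AgeTrendResult:
    """Age trend of DMI from fixed-width age bins.

    Samples are grouped into left-closed, right-open age intervals of
    ``bin_width_years``, anchored at the cohort minimum age floored to a
    multiple of the width. Per bin: mean DMI and a normal-approximation 95%
    CI (undefined and flagged for single-sample bins). A straight line is
    then fitted to (bin midpoint, bin mean); ``r_value``/``p_value`` are the
    Pearson correlation of that fit on the bin means.
    """
    pairs = pd.concat([dmi.rename("dmi"), ages.rename("age")], axis=1).dropna()
    if len(pairs) == 0:
        raise ValueError("no samples with both DMI and age")
    anchor = math.floor(pairs["age"].min() / bin_width_years) * bin_width_years
    idx = ((pairs["age"] - anchor) // bin_width_years).astype(int)
    grouped = pairs.groupby(idx)["dmi"]
    bins = pd.DataFrame(
        {
            "bin_left": anchor + grouped.mean().index * bin_width_years,
            "n": grouped.size(),
            "mean_dmi": grouped.mean(),
            "sd": grouped.std(ddof=1),
        }
    )
    bins["bin_mid"] = bins["bin_left"] + bin_width_years / 2.0
    sem = bins["sd"] / np.sqrt(bins["n"])
    bins["ci_low"] = bins["mean_dmi"] - 1.96 * sem
    bins["ci_high"] = bins["mean_dmi"] + 1.96 * sem
    bins["ci_defined"] = bins["n"] >= 2
    if len(bins) < 3:
        raise ValueError(
            f"need >=3 nonempty age bins, got {len(bins)} "
            f"(bin width {bin_width_years} years)"
        )
    fit = stats.linregress(bins["bin_mid"], bins["mean_dmi"])
    return AgeTrendResult(
        bins=bins.reset_index(drop=True),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        p_value=float(fit.pvalue),
    )
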