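"""Discovery of epigenetically stable loci (ESLs).

An ESL is a CpG whose methylation is nearly invariant across a large cohort
of young, healthy blood donors. The discovery pipeline is:

1. drop blocklisted probes (near SNPs, cross-reactive, age-predictive, sex
   chromosomes, non-CpG targets);
2. rank the remaining probes by cross-cohort β-value variance;
3. keep the least-variable decile;
4. optionally drop candidates showing outlier β in any purified blood cell
   type (guards against loci that only look stable because whole blood
   averages over cell types);
5. split the survivors at β = 0.5 into stably unmethylated vs stably
   methylated, refusing probes in the forbidden intermediate band.

All tie-breaks are lexicographic by probe ID so the pipeline is
deterministic across platforms.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import BLOCKLIST_FLAGS, BetaMatrix

__all__ = [
    "filter_probes",
    "rank_variance",
    "select_stable",
    "filter_purified_outliers",
    "classify_bimodal",
    "discover_esls",
]

logger = logging.getLogger(__name__)


def filter_probes(
    annotation: pd.DataFrame,
    probes: pd.Index | Sequence[str],
    exclude_flags: Iterable[str] = BLOCKLIST_FLAGS,
) -> pd.Index:
    """Return ``probes`` minus every probe with any of ``exclude_flags`` set.

    Every probe must be covered by the annotation; missing probes are a hard
    error (the manifest is the contract for what may enter the analysis).
    """
    probes = pd.Index(probes)
    missing = probes.difference(annotation.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} matrix probes absent from annotation, "
            f"e.g. {missing.tolist()[:5]}"
        )
    exclude_flags = list(exclude_flags)
    unknown = [f for f in exclude_flags if f not in annotation.columns]
    if unknown:
        raise KeyError(f"unknown blocklist flags: {unknown}")
    sub = annotation.loc[probes, exclude_flags]
    flagged = sub.any(axis=1)
    return probes[~flagged.to_numpy()]


def rank_variance(matrix: BetaMatrix) -> pd.DataFrame:
    """Per-probe mean, unbiased variance (n−1 denominator) and variance rank.

    Missing values are dropped per probe; probes with fewer than two
    observations are excluded with a warning. Rank 1 is the smallest
    variance; ties are ordered lexicographically by probe ID, which the
    stable sort below guarantees after pre-sorting the index.
    """
    df = matrix.values
    n_obs = df.notna().sum(axis=1)
    too_few = n_obs < 2
    if too_few.any():
        warnings.warn(
            f"excluding {int(too_few.sum())} probe(s) with <2 observations",
            stacklevel=2,
        )
        df = df.loc[~too_few]
        n_obs = n_obs.loc[~too_few]
    table = pd.DataFrame(
        {
            "mean_beta": df.mean(axis=1),
            "variance": df.var(axis=1, ddof=1),
            "n_obs": n_obs,
        }
    )
    table = table.sort_index(kind="stable").sort_values("variance", kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def select_stable(variance_table: pd.DataFrame, fraction: float = 0.10) -> pd.Index:
    """The ``floor(fraction × n)`` lowest-variance probes.

    Boundary ties were already broken lexicographically by
    :func:`rank_variance`'s deterministic ranking.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    k = math.floor(fraction * len(variance_table))
    return variance_table.index[:k]


def filter_purified_outliers(
    candidates: pd.Index,
    candidate_means: pd.Series,
    purified: Mapping[str, BetaMatrix] | None,
    rule: str = "bounds",
    low_ceiling: float = 0.1,
    high_floor: float = 0.9,
) -> pd.Index:
    """Drop candidates with outlier β in any purified cell type.

    ``candidate_means`` (whole-blood cohort means) decide each candidate's
    pole: mean ≤ 0.5 → low pole, else high pole. Two rules are available:

    * ``bounds`` (default): a low-pole candidate is removed if any purified
      sample's β exceeds ``low_ceiling``; a high-pole candidate if any β
      falls below ``high_floor``.
    * ``tukey``: removed if, within any cell type, any sample lies outside
      the 1.5×IQR Tukey fences of that probe's values in that cell type.

    With no purified data supplied the filter is skipped (logged), since the
    check is a refinement, not a requirement.
    """
    if not purified:
        logger.info("no purified cell-type data supplied; outlier filter skipped")
        return candidates
    if rule not in ("bounds", "tukey"):
        raise ValueError(f"unknown purified-outlier rule {rule!r}")

    low_pole = candidate_means.loc[candidates] <= 0.5
    removed = pd.Series(False, index=candidates)
    for cell_type, matrix in purified.items():
        sub = matrix.select_probes(candidates).values
        if rule == "bounds":
            high = sub.max(axis=1, skipna=True)
            low = sub.min(axis=1, skipna=True)
            bad = np.where(low_pole, high > low_ceiling, low < high_floor)
        else:
            q1 = sub.quantile(0.25, axis=1)
            q3 = sub.quantile(0.75, axis=1)
            iqr = q3 - q1
            bad = (
                sub.lt(q1 - 1.5 * iqr, axis=0) | sub.gt(q3 + 1.5 * iqr, axis=0)
            ).any(axis=1).to_numpy()
        removed |= pd.Series(bad, index=candidates)
    return candidates[~removed.to_numpy()]


def classify_bimodal(
    variance_table: pd.DataFrame,
    stable: pd.Index,
    split: float = 0.5,
    forbidden_band: tuple[float, float] = (0.2, 0.8),
) -> pd.DataFrame:
    """Label stable probes as unmethylated (mean < split) or methylated.

    Stable loci are expected to hug the poles of the β scale; a probe whose
    cohort mean falls strictly inside ``forbidden_band`` contradicts the
    bimodality assumption and is excluded with a warning. The result's
    ``attrs`` record the empty-band extent actually observed (largest
    unmethylated mean, smallest methylated mean).
    """
    if len(stable) == 0:
        raise ValueError("stable set is empty")
    table = variance_table.loc[stable].copy()
    lo, hi = forbidden_band
    in_band = (table["mean_beta"] > lo) & (table["mean_beta"] < hi)
    if in_band.any():
        warnings.warn(
            f"excluding {int(in_band.sum())} stable probe(s) with intermediate "
            f"mean β inside ({lo}, {hi})",
            stacklevel=2,
        )
        table = table.loc[~in_band]
    table["esl_class"] = np.where(
        table["mean_beta"] < split, "unmethylated", "methylated"
    )
    unmeth = table.loc[table["esl_class"] == "unmethylated", "mean_beta"]
    meth = table.loc[table["esl_class"] == "methylated", "mean_beta"]
    table.attrs["unmethylated_max_mean"] = float(unmeth.max()) if len(unmeth) else float("nan")
    table.attrs["methylated_min_mean"] = float(meth.min()) if len(meth) else float("nan")
    return table


def discover_esls(
    matrix: BetaMatrix,
    annotation: pd.DataFrame | None = None,
    fraction: float = 0.10,
    purified: Mapping[str, BetaMatrix] | None = None,
    exclude_flags: Iterable[str] = BLOCKLIST_FLAGS,
    purified_rule: str = "bounds",
    forbidden_band: tuple[float, float] = (0.2, 0.8),
) -> pd.DataFrame:
    """Run the full discovery pipeline and return the ESL table.

    Columns: ``esl_class``, ``mean_beta``, ``variance``, ``n_obs``, ``rank``.
    Variance selection precedes the purified-cell refinement; both counts are
    recorded in ``attrs`` (``n_candidates``, ``n_after_purified``). The
    returned set is asserted free of blocklist flags.
    """
    probes = matrix.probe_ids
    if annotation is not None:
        probes = filter_probes(annotation, probes, exclude_flags)
        matrix = matrix.select_probes(probes)
    vtable = rank_variance(matrix)
    candidates = select_stable(vtable, fraction)
    n_candidates = len(candidates)
    candidates = filter_purified_outliers(
        candidates, vtable["mean_beta"], purified, rule=purified_rule
    )
    esl = classify_bimodal(vtable, candidates, forbidden_band=forbidden_band)
    if annotation is not None:
        flags = annotation.loc[esl.index, list(exclude_flags)]
        assert not flags.any(axis=None), "blocklisted probe survived discovery"
    esl.attrs["n_candidates"] = n_candidates
    esl.attrs["n_after_purified"] = len(candidates)
    return esl
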