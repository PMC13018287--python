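"""Lineage-enriched perturbed loci via exact 2×2 tests.

For each stable locus, perturbation counts in two lineage groups (e.g. the
lymphoid leukemias T-ALL + BCP-ALL vs the myeloid AML) form a 2×2 table
tested with a two-sided Fisher's exact test; Bonferroni correction runs over
the number of tested loci. The odds ratio is oriented so OR > 1 means higher
perturbation odds in the named *target* lineage — fixed here to avoid silent
inversion.

Selection rules:

* lymphoid-enriched — Bonferroni-significant, OR (lymphoid vs myeloid) > 1,
  perturbed in ≥50% of the combined lymphoid samples; rank by OR and keep
  the top half;
* myeloid-enriched — the same significance/OR filters applied separately to
  AML-vs-T-ALL and AML-vs-BCP-ALL (myeloid orientation), intersected, then
  requiring perturbation in ≥10% of AML samples. The extra top-half cut is
  exposed as a flag, off by default.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_per_esl", "select_lymphoid", "select_myeloid"]

logger = logging.getLogger(__name__)


def fisher_per_esl(
    calls: pd.DataFrame,
    groups: pd.Series,
    target: str,
    reference: str,
) -> pd.DataFrame:
    """Per-locus Fisher's exact enrichment of perturbation in ``target``.

    ``calls`` is the binary perturbation grid (loci × samples, NaN missing);
    ``groups`` maps sample → group label. Samples outside the two groups are
    ignored; missing calls drop out of that locus's table. Two-sided p-values
    follow the minimum-likelihood convention (sum of table probabilities no
    larger than the observed table's). The odds ratio is computed from raw
    counts, with a Haldane–Anscombe 0.5 added to every cell only when a zero
    cell occurs, so ranking by OR stays finite.
    """
    groups = groups.reindex(calls.columns)
    t_cols = calls.columns[(groups == target).to_numpy()]
    r_cols = calls.columns[(groups == reference).to_numpy()]
    if len(t_cols) == 0 or len(r_cols) == 0:
        raise ValueError(
            f"both groups must be nonempty (target {target!r}: {len(t_cols)}, "
            f"reference {reference!r}: {len(r_cols)})"
        )
    tc = calls[t_cols]
    rc = calls[r_cols]
    a = (tc == 1.0).sum(axis=1).to_numpy()  # perturbed, target
    b = (tc == 0.0).sum(axis=1).to_numpy()  # unperturbed, target
    c = (rc == 1.0).sum(axis=1).to_numpy()
    d = (rc == 0.0).sum(axis=1).to_numpy()

    n = len(calls)
    pvals = np.empty(n)
    # fisher_exact is table-by-table; cache by counts since cohorts reuse tables
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in range(n):
        key = (int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        if key not in cache:
            cache[key] = float(
                stats.fisher_exact([[key[0], key[1]], [key[2], key[3]]],
                                   alternative="two-sided")[1]
            )
        pvals[i] = cache[key]

    zero_cell = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    af, bf, cf, df = (x + np.where(zero_cell, 0.5, 0.0) for x in (a, b, c, d))
    odds = (af * df) / (bf * cf)

    return pd.DataFrame(
        {
            "perturbed_target": a,
            "unperturbed_target": b,
            "perturbed_reference": c,
            "unperturbed_reference": d,
            "odds_ratio": odds,
            "p_value": pvals,
            "p_bonferroni": np.minimum(1.0, pvals * n),
            "prevalence_target": a / np.maximum(a + b, 1),
            "prevalence_reference": c / np.maximum(c + d, 1),
        },
        index=calls.index,
    )


def _top_by_or(records: pd.DataFrame, top_fraction: float) -> pd.Index:
    """Top ``floor(n × top_fraction)`` loci by OR; ties by smaller p, then ID."""
    k = math.floor(len(records) * top_fraction)
    ordered = (
        records.assign(_id=records.index)
        .sort_values(["odds_ratio", "p_value", "_id"],
                     ascending=[False, True, True], kind="stable")
    )
    return ordered.index[:k]


def select_lymphoid(
    records: pd.DataFrame,
    prevalence_min: float = 0.5,
    alpha: float = 0.05,
    top_fraction: float = 0.5,
) -> pd.Index:
    """Lymphoid-enriched loci from lymphoid-vs-myeloid records.

    ``records`` must be oriented with the combined lymphoid group as target.
    Filters: Bonferroni p < alpha, OR > 1, lymphoid prevalence ≥
    ``prevalence_min``; the survivors are ranked by OR and the top
    ``top_fraction`` kept (floor on odd counts).
    """
    keep = (
        (records["p_bonferroni"] < alpha)
        & (records["odds_ratio"] > 1.0)
        & (records["prevalence_target"] >= prevalence_min)
    )
    candidates = records.loc[keep]
    if candidates.empty:
        logger.info("no lymphoid-enriched candidates passed the filters")
        return pd.Index([], name=records.index.name)
    return _top_by_or(candidates, top_fraction)


def select_myeloid(
    records_vs_tall: pd.DataFrame,
    records_vs_bcpall: pd.DataFrame,
    prevalence_min: float = 0.10,
    alpha: float = 0.05,
    top_fraction: float | None = None,
) -> pd.Index:
    """Myeloid-enriched loci from two pairwise comparisons against AML.

    Both record sets must be oriented with AML as target and share one locus
    universe. Significance + OR filters apply per comparison (optionally with
    a top-fraction OR cut); the intersection is then restricted to loci
    perturbed in at least ``prevalence_min`` of the AML samples.
    """
    if not records_vs_tall.index.equals(records_vs_bcpall.index):
        if len(records_vs_tall.index.intersection(records_vs_bcpall.index)) == 0:
            raise ValueError("record sets have disjoint locus universes")
        raise ValueError("record sets must be computed on the same locus universe")

    def passing(rec: pd.DataFrame) -> pd.Index:
        keep = (rec["p_bonferroni"] < alpha) & (rec["odds_ratio"] > 1.0)
        sub = rec.loc[keep]
        if top_fraction is not None:
            return _top_by_or(sub, top_fraction)
        return sub.index

    hit = passing(records_vs_tall).intersection(passing(records_vs_bcpall))
    prev = records_vs_tall.loc[hit, "prevalence_target"]
    selected = hit[(prev >= prevalence_min).to_numpy()]
    if len(selected) == 0:
        logger.info("no myeloid-enriched loci passed the filters")
    return selected
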