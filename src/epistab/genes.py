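"""Gene prioritization from promoter-locus methylation, expression and age.

Genes most plausibly silenced through destabilization of their promoter
loci satisfy three criteria simultaneously:

1. expression falls significantly with promoter methylation (negative
   Pearson r between locus β and the gene's expression);
2. expression falls significantly with donor age;
3. the gene's promoter loci are recurrently perturbed (mean recurrence
   strictly above 5%).

Promoter assignment for prioritization uses an upstream-only window
(−1500 bp ≤ TSS distance ≤ 0); the genomic-context enrichment report uses
the symmetric ±1500 bp promoter definition. Expression is log2(x + 1)
transformed before correlation by default (TPM-like inputs). Multiple
testing is Bonferroni throughout: over all tested loci for the
methylation–expression criterion and over genes for the age criterion.

Gene-level significance for the methylation criterion follows an explicit
convention: each locus is tested separately, and a gene qualifies when its
mean r is negative and at least one of its loci has a Bonferroni-significant
negative correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix

__all__ = [
    "map_promoter_esls",
    "correlate_meth_expr",
    "correlate_age_expr",
    "build_gene_records",
    "prioritize",
    "context_enrichment",
    "ContextEnrichment",
]

logger = logging.getLogger(__name__)


def map_promoter_esls(
    esl_probes: pd.Index,
    annotation: pd.DataFrame,
    upstream_bp: int = 1500,
    downstream_bp: int = 0,
) -> dict[str, list[str]]:
    """Map genes to their promoter loci by signed TSS distance.

    A locus belongs to its nearest gene's promoter iff
    ``−upstream_bp ≤ tss_distance ≤ downstream_bp`` (negative = upstream).
    Loci with missing TSS distance are skipped with a logged count.
    """
    ann = annotation.loc[annotation.index.intersection(esl_probes)]
    missing = ann["tss_distance"].isna()
    if missing.any():
        logger.info("skipping %d loci with missing tss_distance", int(missing.sum()))
        ann = ann.loc[~missing]
    in_window = (ann["tss_distance"] >= -upstream_bp) & (
        ann["tss_distance"] <= downstream_bp
    )
    mapped = ann.loc[in_window]
    out: dict[str, list[str]] = {}
    for probe, gene in mapped["nearest_gene"].items():
        out.setdefault(str(gene), []).append(probe)
    return {g: sorted(ps) for g, ps in sorted(out.items())}


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided t-test p for paired rows of X and Y."""
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * Yc).sum(axis=1) / denom
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(r)] = np.nan
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def _log_tpm(x: np.ndarray) -> np.ndarray:
    return np.log2(x + 1.0)


def correlate_meth_expr(
    matrix: BetaMatrix,
    expression: pd.DataFrame,
    gene_map: dict[str, list[str]],
    log_transform: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene mean methylation–expression correlation.

    For every promoter locus, Pearson r between its β and the gene's
    expression across shared samples; genes with several loci get the mean
    r. ``p_meth`` is the smallest Bonferroni-adjusted p (over all tested
    loci) among the gene's negatively correlated loci, and
    ``significant_negative`` applies the gene-level convention documented in
    the module docstring.
    """
    shared = matrix.sample_ids.intersection(expression.columns)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    probes, genes_of = [], []
    for gene, ps in gene_map.items():
        if gene not in expression.index:
            continue
        for p_ in ps:
            probes.append(p_)
            genes_of.append(gene)
    if not probes:
        return pd.DataFrame(
            columns=["mean_r_meth", "p_meth", "n_esls", "significant_negative"]
        )
    X = matrix.select_probes(pd.Index(probes)).values[shared].to_numpy()
    expr = expression.loc[genes_of, shared].to_numpy(dtype=float)
    if log_transform:
        expr = _log_tpm(expr)
    r, p = _rowwise_pearson(X, expr)
    n_tests = np.isfinite(r).sum()
    p_adj = np.minimum(1.0, p * n_tests)
    per_locus = pd.DataFrame(
        {"gene": genes_of, "r": r, "p_adj": p_adj}, index=pd.Index(probes)
    ).dropna(subset=["r"])

    def summarize(sub: pd.DataFrame) -> pd.Series:
        neg = sub[sub["r"] < 0]
        p_min = float(neg["p_adj"].min()) if len(neg) else np.nan
        mean_r = float(sub["r"].mean())
        return pd.Series(
            {
                "mean_r_meth": mean_r,
                "p_meth": p_min,
                "n_esls": len(sub),
                "significant_negative": mean_r < 0 and len(neg) > 0
                and float(neg["p_adj"].min()) < alpha,
            }
        )

    out = per_locus.groupby("gene").apply(summarize, include_groups=False)
    out["n_esls"] = out["n_esls"].astype(int)
    out["significant_negative"] = out["significant_negative"].astype(bool)
    out.index.name = "gene"
    return out


def correlate_age_expr(
    expression: pd.DataFrame,
    ages: pd.Series,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene Pearson correlation between expression and donor age.

    Bonferroni adjustment runs over the genes tested. Constant-expression
    genes are skipped (NaN) with a logged count.
    """
    shared = expression.columns.intersection(ages.dropna().index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} samples with ages; need at least 3")
    expr = expression[shared].to_numpy(dtype=float)
    if log_transform:
        expr = _log_tpm(expr)
    age = ages.loc[shared].to_numpy(dtype=float)
    constant = expr.std(axis=1) == 0
    if constant.any():
        logger.info("skipping %d constant-expression genes", int(constant.sum()))
    A = np.broadcast_to(age, expr.shape)
    r, p = _rowwise_pearson(expr, A)
    r[constant] = np.nan
    p[constant] = np.nan
    n_tests = np.isfinite(r).sum()
    return pd.DataFrame(
        {
            "r_age": r,
            "p_age": p,
            "p_age_bonferroni": np.minimum(1.0, p * n_tests),
        },
        index=expression.index,
    )


def build_gene_records(
    meth_corr: pd.DataFrame,
    age_corr: pd.DataFrame,
    recurrence_frac: pd.Series,
    gene_map: dict[str, list[str]],
) -> pd.DataFrame:
    """Join the three per-gene criteria into one record table."""
    mean_rec = pd.Series(
        {g: float(recurrence_frac.reindex(ps).mean()) for g, ps in gene_map.items()},
        name="mean_recurrence",
    )
    records = meth_corr.join(age_corr, how="inner").join(mean_rec, how="left")
    records.index.name = "gene"
    return records


def prioritize(
    records: pd.DataFrame,
    alpha: float = 0.05,
    recurrence_min: float = 0.05,
) -> pd.DataFrame:
    """Apply the three-way conjunction and flag prioritized genes."""
    if records.empty:
        out = records.copy()
        out["prioritized"] = pd.Series(dtype=bool)
        return out
    out = records.copy()
    out["prioritized"] = (
        out["significant_negative"].fillna(False)
        & (out["r_age"] < 0)
        & (out["p_age_bonferroni"] < alpha)
        & (out["mean_recurrence"] > recurrence_min)
    )
    return out


@dataclass
class ContextEnrichment:
    """Genomic-context summary of a stable-locus set vs the array background."""

    island_odds_ratio: float
    island_p: float
    island_counts: tuple[int, int, int, int]  # esl-island, esl-other, bg-island, bg-other
    tss_fraction: float
    tss_window_bp: int


def context_enrichment(
    esl_probes: pd.Index,
    annotation: pd.DataFrame,
    tss_window_bp: int = 1500,
) -> ContextEnrichment:
    """CpG-island enrichment and TSS proximity of a stable-locus set.

    The 2×2 table crosses membership in ``esl_probes`` against island
    residency, with all other annotated probes as background; the odds ratio
    is the raw cross-product ratio and p a two-sided Fisher's exact test.
    ``tss_fraction`` is the share of the set within ±``tss_window_bp`` of a
    TSS (symmetric promoter window).
    """
    esl_probes = pd.Index(esl_probes)
    in_set = annotation.index.isin(esl_probes)
    if not in_set.any():
        raise ValueError("no annotated probes in the stable set")
    if in_set.all():
        raise ValueError("background is empty: annotation covers only the stable set")
    island = (annotation["cgi_relation"] == "island").to_numpy()
    a = int((in_set & island).sum())
    b = int((in_set & ~island).sum())
    c = int((~in_set & island).sum())
    d = int((~in_set & ~island).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        or_ = (a * d) / (b * c) if b * c > 0 else np.inf
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    tss = annotation.loc[annotation.index[in_set], "tss_distance"].abs()
    frac = float((tss <= tss_window_bp).mean())
    return ContextEnrichment(
        island_odds_ratio=float(or_),
        island_p=float(p),
        island_counts=(a, b, c, d),
        tss_fraction=frac,
        tss_window_bp=tss_window_bp,
    )
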