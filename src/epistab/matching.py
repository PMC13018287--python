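"""Diagnosis–relapse epi-clone matching with a permutation null.

The test of somatic methylation inheritance: if a patient's perturbed
low-recurrence loci mark a heritable epi-clone, the diagnosis and relapse
samples of the same patient should cluster together on those loci. The
procedure, per patient, takes the k (default 15) low-recurrence loci with
the highest β in the relapse sample, pools the union of all patients'
signatures, computes pairwise sample dissimilarity 1 − Pearson r, and builds
a Ward dendrogram. A patient is *correctly paired* when its diagnosis and
relapse samples are merged as immediate siblings — the parameter-free
reading of pairing from a dendrogram (a mutual-nearest-neighbour criterion
is available behind a flag).

Significance comes from a permutation null: in each of ``n_sims``
simulations, k *random* low-recurrence loci are drawn per patient, the union
matrix is re-clustered, and correct pairs are re-counted; the p-value is the
proportion of simulations whose count equals or exceeds the observed one.
(That exceedance proportion is a one-tailed quantity even when reported
alongside two-sided language; the definition implemented is the proportion
stated.) No +1 correction is applied by default; the standard
(b + 1)/(m + 1) estimator is available via ``plus_one``.

Ward linkage formally presumes squared Euclidean distances; running it on a
correlation-based dissimilarity is a pragmatic convention adopted here
deliberately, with this caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core_io import BetaMatrix

__all__ = [
    "select_signature",
    "cluster_and_pair",
    "permutation_test",
    "MatchingResult",
    "PermutationResult",
]


def select_signature(beta: pd.Series, k: int = 15) -> pd.Index:
    """The k loci with the largest β in one sample; ties broken by probe ID."""
    usable = beta.dropna()
    if len(usable) < k:
        raise ValueError(f"only {len(usable)} usable loci, need k={k}")
    order = (
        usable.rename("beta").to_frame()
        .assign(_id=usable.index)
        .sort_values(["beta", "_id"], ascending=[False, True], kind="stable")
    )
    return order.index[:k]


@dataclass
class MatchingResult:
    """Dendrogram-derived pairing of diagnosis and relapse samples."""

    signatures: dict[str, pd.Index]
    linkage_matrix: np.ndarray
    sample_order: list[str]
    pairs: list[tuple[str, str]]
    n_correct: int
    n_patients: int
    p_value: float | None = None
    n_sims: int | None = None
    seed: int | None = None


@dataclass
class PermutationResult:
    p_value: float
    n_sims: int
    null_counts: np.ndarray = field(repr=False)
    observed: int = 0
    seed: int | None = None


def _sibling_pairs(link: np.ndarray, n: int) -> set[frozenset[int]]:
    """Leaf pairs merged directly with each other (both children original)."""
    merged = link[:, :2].astype(int)
    both_leaves = (merged[:, 0] < n) & (merged[:, 1] < n)
    return {frozenset(row) for row in merged[both_leaves]}


def _mnn_pairs(dist: np.ndarray) -> set[frozenset[int]]:
    """Mutual nearest neighbours by distance."""
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    return {frozenset((i, nn[i])) for i in range(len(nn)) if nn[nn[i]] == i}


def _count_correct(
    profiles: np.ndarray,
    dx_pos: np.ndarray,
    rel_pos: np.ndarray,
    method: str = "sibling",
    sample_ids: list[str] | None = None,
) -> tuple[int, np.ndarray, set[frozenset[int]]]:
    """Cluster sample ``profiles`` (samples × loci) and count correct pairs."""
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        which = int(np.flatnonzero(sd == 0)[0])
        name = sample_ids[which] if sample_ids else str(which)
        raise ValueError(f"constant profile for sample {name!r}: correlation undefined")
    corr = np.corrcoef(profiles)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = linkage(squareform(dist, checks=False), method="ward")
    if method == "sibling":
        pairs = _sibling_pairs(link, profiles.shape[0])
    elif method == "mnn":
        pairs = _mnn_pairs(dist)
    else:
        raise ValueError(f"unknown pairing method {method!r}")
    n_correct = sum(
        frozenset((int(d), int(r))) in pairs for d, r in zip(dx_pos, rel_pos)
    )
    return n_correct, link, pairs


def _patient_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with its diagnosis and relapse sample IDs."""
    sub = meta[meta["timepoint"].isin(["diagnosis", "relapse"])]
    wide = sub.reset_index().pivot(index="patient_id", columns="timepoint",
                                   values="sample_id")
    if wide.isna().any(axis=None):
        bad = wide[wide.isna().any(axis=1)].index.tolist()[:5]
        raise ValueError(f"patients missing diagnosis or relapse samples: {bad}")
    return wide


def cluster_and_pair(
    matrix: BetaMatrix,
    meta: pd.DataFrame,
    low_recurrence_probes: pd.Index,
    k: int = 15,
    signature_from: str = "relapse",
    method: str = "sibling",
) -> MatchingResult:
    """Signature selection, Ward clustering and correct-pair counting.

    ``meta`` must provide ``patient_id`` and ``timepoint`` per sample, with
    one diagnosis and one relapse sample per patient. Signatures are taken
    from the relapse sample by default (``signature_from="diagnosis"``
    switches to the diagnosis-side variant of the analysis).
    """
    if signature_from not in ("relapse", "diagnosis"):
        raise ValueError(f"signature_from must be 'relapse' or 'diagnosis'")
    wide = _patient_samples(meta)
    pool = matrix.select_probes(pd.Index(low_recurrence_probes))

    signatures: dict[str, pd.Index] = {}
    for patient, row in wide.iterrows():
        sig_sample = row[signature_from]
        signatures[patient] = select_signature(pool.values[sig_sample], k)

    union = pd.Index(sorted(set().union(*[set(s) for s in signatures.values()])))
    sample_ids = [s for pair in wide.itertuples(index=False) for s in pair]
    sub = pool.select_probes(union).select_samples(sample_ids)
    profiles = sub.values.to_numpy().T  # samples × loci

    pos = {s: i for i, s in enumerate(sample_ids)}
    dx_pos = np.array([pos[s] for s in wide["diagnosis"]])
    rel_pos = np.array([pos[s] for s in wide["relapse"]])
    n_correct, link, pairs = _count_correct(
        profiles, dx_pos, rel_pos, method=method, sample_ids=sample_ids
    )
    named_pairs = [
        tuple(sorted(sample_ids[i] for i in pair)) for pair in pairs
    ]
    return MatchingResult(
        signatures=signatures,
        linkage_matrix=link,
        sample_order=sample_ids,
        pairs=sorted(named_pairs),
        n_correct=n_correct,
        n_patients=len(wide),
    )


def permutation_test(
    matrix: BetaMatrix,
    meta: pd.DataFrame,
    observed: int,
    low_recurrence_probes: pd.Index,
    k: int = 15,
    n_sims: int = 1000,
    seed: int = 0,
    method: str = "sibling",
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation p-value for an observed correct-pair count.

    Each simulation draws k loci per patient uniformly without replacement
    from the low-recurrence pool, rebuilds the union profile matrix,
    re-clusters, and counts correct pairs. p = #{count ≥ observed} / n_sims
    (or the (b+1)/(m+1) variant with ``plus_one``). A single seeded
    generator drives all draws, so results are reproducible and invariant to
    patient order.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    pool = pd.Index(low_recurrence_probes)
    if len(pool) < k:
        raise ValueError(f"low-recurrence pool ({len(pool)}) smaller than k={k}")
    wide = _patient_samples(meta).sort_index()
    sample_ids = [s for pair in wide.itertuples(index=False) for s in pair]
    base = matrix.select_probes(pool).select_samples(sample_ids)
    vals = base.values.to_numpy()  # pool × samples
    pos = {s: i for i, s in enumerate(sample_ids)}
    dx_pos = np.array([pos[s] for s in wide["diagnosis"]])
    rel_pos = np.array([pos[s] for s in wide["relapse"]])

    rng = np.random.default_rng(seed)
    n_patients = len(wide)
    counts = np.empty(n_sims, dtype=int)
    for s in range(n_sims):
        draws = np.concatenate(
            [rng.choice(len(pool), size=k, replace=False) for _ in range(n_patients)]
        )
        idx = np.unique(draws)
        profiles = vals[idx].T
        counts[s], _, _ = _count_correct(profiles, dx_pos, rel_pos, method=method)
    hits = int((counts >= observed).sum())
    p = (hits + 1) / (n_sims + 1) if plus_one else hits / n_sims
    return PermutationResult(
        p_value=float(p), n_sims=n_sims, null_counts=counts,
        observed=observed, seed=seed,
    )
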