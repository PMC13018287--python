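"""End-to-end validation benchmarks on synthetic cohorts with planted truth.

Each function runs one slice of the pipeline at a stated problem size,
measures how well the planted structure is recovered (or how exactly an
operation matches an independent brute-force oracle), and returns plain
numbers. The test suite asserts on these numbers; the reproduction script
writes them out. Every function takes a ``seed`` so runs are reproducible,
and derives all internal randomness from it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate as sim
from .core_io import BetaMatrix
from .destabilize import binarize, calibrate_threshold, recurrence
from .discovery import discover_esls
from .dmi import compute_dmi
from .genes import (
    build_gene_records,
    correlate_age_expr,
    correlate_meth_expr,
    map_promoter_esls,
    prioritize,
)
from .lineage import fisher_per_esl
from .matching import cluster_and_pair, permutation_test
from .survival import cox_adjusted, power_sample_size

__all__ = [
    "threshold_percentile_max_error",
    "esl_recovery",
    "dmi_monotonicity",
    "matching_power",
    "matching_null_calibration",
    "fisher_enumeration_max_error",
    "lineage_null_false_positives",
    "cox_recovery",
    "power_monotonicity",
    "prioritization_recovery",
    "prioritization_null_rate",
]


def _spawn(seed: int, k: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=k)]


# ---------------------------------------------------------------------------
# threshold calibration vs sort-and-interpolate oracle

def _percentile_oracle(values: np.ndarray, q: float) -> float:
    x = np.sort(np.asarray(values, dtype=float))
    h = (len(x) - 1) * (q / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(x) - 1)
    return float(x[lo] + (h - lo) * (x[hi] - x[lo]))


def threshold_percentile_max_error(n_vectors: int = 1000, seed: int = 0) -> float:
    """Max |calibrated threshold − oracle| over random pooled mean vectors.

    Pools are realized as one-sample control cohorts, whose per-locus means
    equal the pooled values exactly, so the comparison isolates the
    percentile step. Vector lengths and percentiles vary per draw.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 400))
        values = rng.random(n)
        q = float(rng.choice([50.0, 90.0, 99.0, 99.9]))
        cohort = BetaMatrix(pd.DataFrame(
            {"s1": values}, index=[f"cg{i:05d}" for i in range(n)]
        ))
        got = calibrate_threshold([cohort], percentile=q)
        worst = max(worst, abs(got - _percentile_oracle(values, q)))
    return worst


# ---------------------------------------------------------------------------
# stable-locus discovery on planted cohorts

def esl_recovery(
    n_seeds: int = 20,
    n_probes: int = 10_000,
    n_samples: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Precision/recall of discovery against the planted stable set.

    Each replicate simulates a fresh young-healthy cohort (10% planted
    stable probes, fresh genome layout per replicate) and runs the variance
    pipeline at the matching selection fraction.
    """
    precisions, recalls = [], []
    for s in _spawn(seed, n_seeds):
        cfg = sim.SimulationConfig(
            n_probes=n_probes, n_samples=n_samples, layout_seed=s + 1
        )
        matrix, _, truth = sim.simulate_cohort(cfg, seed=s)
        esl = discover_esls(matrix, fraction=0.10)
        found, planted = set(esl.index), set(truth.stable)
        precisions.append(len(found & planted) / len(found))
        recalls.append(len(found & planted) / len(planted))
    return {
        "min_precision": float(min(precisions)),
        "min_recall": float(min(recalls)),
        "mean_precision": float(np.mean(precisions)),
        "mean_recall": float(np.mean(recalls)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# DMI dose–response in clone fraction

def dmi_monotonicity(
    n_replicates: int = 50,
    n_probes: int = 2000,
    n_samples: int = 10,
    seed: int = 0,
) -> dict[str, float | list[float]]:
    """Spearman ρ between clone fraction and mean DMI across the 0–0.9 grid.

    The instability score is computed over the unmethylated stable loci
    discovered once from a clone-free cohort sharing the same genome layout.
    """
    cfg0 = sim.SimulationConfig(n_probes=n_probes, n_samples=300)
    matrix, _, _ = sim.simulate_cohort(cfg0, seed=seed)
    esl = discover_esls(matrix, fraction=0.10)
    unmeth = esl.index[esl["esl_class"] == "unmethylated"]

    fractions = np.round(np.arange(0.0, 1.0, 0.1), 1)
    seeds = iter(_spawn(seed + 1, len(fractions) * n_replicates))
    means = []
    for f in fractions:
        cfg = sim.SimulationConfig(n_probes=n_probes, n_samples=n_samples)
        rep_means = [
            compute_dmi(
                sim.simulate_cohort(cfg, seed=next(seeds),
                                    clone_fractions=np.full(n_samples, f))[0],
                unmeth, "all",
            )["dmi"].mean()
            for _ in range(n_replicates)
        ]
        means.append(float(np.mean(rep_means)))
    rho = stats.spearmanr(fractions, means).statistic
    return {"spearman_rho": float(rho), "mean_dmi_by_fraction": means,
            "strictly_increasing": bool(np.all(np.diff(means) > 0))}


# ---------------------------------------------------------------------------
# diagnosis–relapse matching: power and permutation-null calibration

def _matching_config(n_probes: int, f_range: tuple[float, float],
                     layout_seed: int = 0) -> sim.SimulationConfig:
    # the matrix stands for the low-recurrence stable-locus pool itself, so
    # nearly all probes are stable-low
    return sim.SimulationConfig(
        n_probes=n_probes, fraction_stable_unmeth=0.9,
        fraction_stable_meth=0.02, signature_size=15,
        clone_fraction_range=f_range, layout_seed=layout_seed,
    )


def matching_power(
    n_replicates: int = 100,
    n_patients: int = 24,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of planted cohorts in which every pair is matched correctly.

    Cohorts mirror a strongly clonal leukemia series: clone fractions ≥ 0.3
    and 15-locus patient signatures, disjoint across patients.
    """
    all_correct = 0
    for s in _spawn(seed, n_replicates):
        cfg = _matching_config(2000, (0.3, 0.9), layout_seed=s + 1)
        m, meta, truth = sim.simulate_longitudinal_cohort(
            cfg, n_patients, seed=s, include_remission=False
        )
        res = cluster_and_pair(m, meta, truth.stable_low, k=15)
        all_correct += res.n_correct == n_patients
    return {"all_correct_rate": all_correct / n_replicates,
            "n_replicates": n_replicates}


def matching_null_calibration(
    n_runs: int = 500,
    n_sims: int = 200,
    n_patients: int = 24,
    seed: int = 0,
) -> dict[str, float]:
    """Uniformity of the permutation p-value on clone-free cohorts.

    Each run simulates a null cohort (clone fraction 0), computes the
    observed correct-pair count through the full top-k signature pipeline,
    and runs the permutation test. Because the correct-pair count is
    discrete, uniformity is assessed on the tie-randomized probability
    integral transform — the standard exactly-uniform construction for
    Monte-Carlo p-values — and summarized by a Kolmogorov–Smirnov test.
    """
    rng = np.random.default_rng(seed)
    seeds = _spawn(seed + 1, 2 * n_runs)
    pit = np.empty(n_runs)
    plain = np.empty(n_runs)
    for i in range(n_runs):
        cfg = _matching_config(2000, (0.0, 0.0), layout_seed=i)
        m, meta, truth = sim.simulate_longitudinal_cohort(
            cfg, n_patients, seed=seeds[2 * i], include_remission=False
        )
        obs = cluster_and_pair(m, meta, truth.stable_low, k=15).n_correct
        perm = permutation_test(
            m, meta, obs, truth.stable_low, k=15,
            n_sims=n_sims, seed=seeds[2 * i + 1],
        )
        plain[i] = perm.p_value
        greater = int((perm.null_counts > obs).sum())
        ties = int((perm.null_counts == obs).sum())
        # rank of the observed draw among the n_sims + 1 exchangeable draws,
        # ties broken uniformly: exactly uniform when the test is calibrated
        rank = greater + rng.integers(0, ties + 1) + 1
        pit[i] = rank / (n_sims + 1)
    ks = stats.kstest(pit, "uniform")
    return {
        "ks_p_value": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "mean_plain_p": float(plain.mean()),
        "n_runs": n_runs,
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# Fisher exact p vs exhaustive hypergeometric enumeration

def _two_sided_hypergeom(a: int, b: int, c: int, d: int) -> float:
    n1, n2, m = a + b, c + d, a + c
    if n1 + n2 == 0:  # the empty table carries no evidence
        return 1.0
    support = np.arange(max(0, m - n2), min(n1, m) + 1)
    pmf = stats.hypergeom.pmf(support, n1 + n2, n1, m)
    p_obs = stats.hypergeom.pmf(a, n1 + n2, n1, m)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def fisher_enumeration_max_error(max_total: int = 30) -> dict[str, float]:
    """Max |p − oracle| over every 2×2 table of total size ≤ ``max_total``.

    Every margin of such a table is ≤ ``max_total``. The oracle enumerates
    the hypergeometric distribution with fixed margins and sums the
    probabilities of tables no more likely than the observed one; the
    implementation path is the per-locus enrichment routine itself.
    """
    tables = [
        (a, b, c, d)
        for a in range(max_total + 1)
        for b in range(max_total + 1 - a)
        for c in range(max_total + 1 - a - b)
        for d in range(max_total + 1 - a - b - c)
    ]
    n_t = max(a + b for a, b, _, _ in tables)
    n_r = max(c + d for _, _, c, d in tables)
    rows, cols = [], None
    for a, b, c, d in tables:
        rows.append([1.0] * a + [0.0] * b + [np.nan] * (n_t - a - b)
                    + [1.0] * c + [0.0] * d + [np.nan] * (n_r - c - d))
    cols = [f"t{i}" for i in range(n_t)] + [f"r{i}" for i in range(n_r)]
    calls = pd.DataFrame(rows, columns=cols,
                         index=[f"cg{i:06d}" for i in range(len(tables))])
    groups = pd.Series(["T"] * n_t + ["R"] * n_r, index=cols)
    rec = fisher_per_esl(calls, groups, "T", "R")
    oracle = np.array([_two_sided_hypergeom(*t) for t in tables])
    err = np.abs(rec["p_value"].to_numpy() - oracle)
    return {"max_abs_error": float(err.max()), "n_tables": len(tables)}


# ---------------------------------------------------------------------------
# lineage enrichment: false positives under permuted labels

def lineage_null_false_positives(
    n_datasets: int = 200,
    n_samples: int = 60,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of Bonferroni-significant loci when lineage labels are random.

    Cancer cohorts are simulated with real clonal perturbation, binarized at
    a threshold calibrated from clone-free controls, and then tested with
    labels assigned by permutation — so any detected 'enrichment' is a false
    positive.
    """
    cfg0 = sim.SimulationConfig(n_probes=2000, n_samples=300)
    matrix, _, _ = sim.simulate_cohort(cfg0, seed=seed)
    esl = discover_esls(matrix, fraction=0.10)
    unmeth = esl.index[esl["esl_class"] == "unmethylated"]
    ctrl_cfg = sim.SimulationConfig(n_probes=2000, n_samples=100)
    controls = [
        sim.simulate_cohort(ctrl_cfg, seed=s)[0].select_probes(unmeth)
        for s in _spawn(seed + 1, 3)
    ]
    thr = calibrate_threshold(controls)

    rng = np.random.default_rng(seed + 2)
    n_sig = n_tested = 0
    for s in _spawn(seed + 3, n_datasets):
        cfg = sim.SimulationConfig.cancer_cohort(
            n_probes=2000, n_samples=n_samples, coupled_perturbation=True
        )
        cancer, _, _ = sim.simulate_cohort(cfg, seed=s)
        calls = binarize(cancer.select_probes(unmeth), thr)
        labels = np.array(["lymphoid"] * (n_samples // 2)
                          + ["myeloid"] * (n_samples - n_samples // 2))
        rng.shuffle(labels)
        groups = pd.Series(labels, index=calls.columns)
        rec = fisher_per_esl(calls, groups, "lymphoid", "myeloid")
        n_sig += int((rec["p_bonferroni"] < 0.05).sum())
        n_tested += len(rec)
    return {"significant_fraction": n_sig / n_tested,
            "n_datasets": n_datasets, "n_loci_per_dataset": n_tested // n_datasets}


# ---------------------------------------------------------------------------
# survival: Cox recovery and power-curve monotonicity

def cox_recovery(
    n_replicates: int = 100,
    n: int = 2000,
    hazard_ratio: float = 1.5,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> dict[str, float]:
    """Bias of the Cox log-HR estimate and 95% CI coverage on planted cohorts."""
    cfg = sim.SimulationConfig(
        log_hr_high=float(np.log(hazard_ratio)), censoring_rate=censoring_rate
    )
    labels = pd.Series(["high"] * (n // 2) + ["low"] * (n - n // 2))
    target = np.log(hazard_ratio)
    errors, covered = [], 0
    for s in _spawn(seed, n_replicates):
        surv = sim.simulate_survival_cohort(cfg, labels, seed=s)
        fit = cox_adjusted(surv, ["high"])
        errors.append(fit.loc["high", "coef"] - target)
        covered += fit.loc["high", "ci_low"] <= hazard_ratio <= fit.loc["high", "ci_high"]
    return {
        "loghr_bias": float(np.mean(errors)),
        "ci_coverage": covered / n_replicates,
        "n_replicates": n_replicates,
    }


def power_monotonicity(n_iterations: int = 150, seed: int = 0) -> dict:
    """Required sample size across hazard ratios, and power across n.

    Larger planted effects need fewer patients, and more patients never hurt
    power beyond Monte-Carlo error.
    """
    grids = {1.5: (64, 128, 256, 512, 1024), 2.0: (32, 64, 128, 256),
             3.0: (16, 32, 64, 128)}
    required = {}
    tables = {}
    for hr, grid in grids.items():
        res = power_sample_size(
            hazard_ratio=hr, n_grid=grid, n_iterations=n_iterations, seed=seed
        )
        required[hr] = res.required_n
        tables[hr] = res.table
    full = power_sample_size(
        target_power=0.999, hazard_ratio=1.5, n_grid=(64, 256, 1024),
        n_iterations=n_iterations, seed=seed + 1,
    ).table
    monotone_in_n = all(
        full["power"].iloc[i + 1] >= full["power"].iloc[i]
        - 2 * (full["mc_se"].iloc[i] + full["mc_se"].iloc[i + 1])
        for i in range(len(full) - 1)
    )
    return {
        "required_n_by_hr": required,
        "monotone_in_hr": bool(required[1.5] >= required[2.0] >= required[3.0]),
        "monotone_in_n": bool(monotone_in_n),
        "power_table_hr15": full,
    }


# ---------------------------------------------------------------------------
# gene prioritization: planted silencing and fully-null calibration

def _prioritize_once(n_genes: int, n_planted: int, n_samples: int,
                     seed: int, layout_seed: int = 0):
    cfg = sim.SimulationConfig(layout_seed=layout_seed)
    bm, expr, ages, ann, planted = sim.simulate_expression_cohort(
        n_genes, n_planted, n_samples, seed=seed, config=cfg
    )
    bm_ctrl, _, _, _, _ = sim.simulate_expression_cohort(
        n_genes, 0, 100, seed=seed + 1, config=cfg
    )
    thr = calibrate_threshold([bm_ctrl], 99.9)
    rec = recurrence(binarize(bm, thr))
    gene_map = map_promoter_esls(bm.probe_ids, ann)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        meth = correlate_meth_expr(bm, expr, gene_map)
    age = correlate_age_expr(expr, ages)
    out = prioritize(build_gene_records(meth, age, rec["recurrence"], gene_map))
    return set(out.index[out["prioritized"]]), set(planted)


def prioritization_recovery(
    n_seeds: int = 10,
    n_genes: int = 300,
    n_planted: int = 30,
    n_samples: int = 120,
    seed: int = 0,
) -> dict[str, float]:
    """Precision/recall of the three-criterion gene screen at strong effects."""
    precisions, recalls = [], []
    for i, s in enumerate(_spawn(seed, n_seeds)):
        selected, planted = _prioritize_once(
            n_genes, n_planted, n_samples, seed=s, layout_seed=i
        )
        tp = len(selected & planted)
        precisions.append(tp / max(len(selected), 1))
        recalls.append(tp / len(planted))
    return {
        "mean_precision": float(np.mean(precisions)),
        "mean_recall": float(np.mean(recalls)),
        "min_precision": float(min(precisions)),
        "min_recall": float(min(recalls)),
        "n_seeds": n_seeds,
    }


def prioritization_null_rate(
    n_replicates: int = 200,
    n_genes: int = 500,
    n_samples: int = 120,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of fully-null replicates with zero prioritized genes."""
    zero = 0
    for i, s in enumerate(_spawn(seed, n_replicates)):
        selected, _ = _prioritize_once(n_genes, 0, n_samples, seed=s,
                                       layout_seed=1000 + i)
        zero += len(selected) == 0
    return {"zero_fraction": zero / n_replicates, "n_replicates": n_replicates}
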