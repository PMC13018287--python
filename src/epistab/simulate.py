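"""Synthetic β-value cohorts with planted truth.

The generator is a forward model of the structure the pipeline is built to
detect, not of array chemistry. Probes fall into three classes: stably
unmethylated (β concentrated near 0), stably methylated (β near 1), and
variable (β dispersed across the unit interval). Per-probe noise is drawn
from beta distributions — the natural family for bounded methylation
fractions — parameterized by a class mean and a concentration.

Clonal perturbation follows a two-population mixture: a sample carrying an
expanded clone of cell fraction ``f`` with a patient-specific signature of
normally unmethylated loci has, at each signature locus,

    β = (1 − f) · β_background + f · β_clone,

so the expected β is affine in ``f`` — the property every downstream
monotonicity check rests on. Ageing is modelled as the accumulation of small
clones: the number of perturbed stable loci per sample grows linearly with
age, which plants an instability–age trend. Survival times follow an
exponential proportional-hazards model with a configurable log hazard ratio
for the high-instability group and independent exponential censoring.

All randomness flows from a single ``numpy`` generator seeded per call:
identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_io import BetaMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_longitudinal_cohort",
    "simulate_survival_cohort",
    "simulate_probe_annotation",
    "simulate_expression_cohort",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a young-healthy discovery cohort: everyone aged 18,
    no clonal expansions, 10% of probes planted stable (8% at the low pole,
    2% at the high pole, matching the observed predominance of stably
    unmethylated loci).
    """

    n_probes: int = 10_000
    n_samples: int = 500
    fraction_stable_unmeth: float = 0.08
    fraction_stable_meth: float = 0.02

    # Pole-concentrated background noise. Each stable probe has its own mean
    # drawn from a Beta with mean ``stable_low_mean`` and concentration
    # ``stable_mean_concentration`` (mirrored at the high pole), reproducing
    # the observed pole-hugging distribution of stable-locus means; per-value
    # noise around the probe mean uses ``stable_concentration`` (a
    # Beta(m*k, (1-m)*k) has variance m(1-m)/(k+1)).
    stable_low_mean: float = 0.015
    stable_high_mean: float = 0.985
    stable_mean_concentration: float = 150.0
    stable_concentration: float = 300.0
    variable_mean_range: tuple[float, float] = (0.05, 0.95)
    variable_concentration: float = 10.0

    # Clone model: signature loci are sampled from the stable-low pool,
    # mimicking perturbation of normally unmethylated loci.
    clone_prevalence: float = 0.0
    clone_fraction_range: tuple[float, float] = (0.3, 0.9)
    signature_size: int = 15
    clone_meth_mean: float = 0.85
    clone_meth_concentration: float = 50.0

    # Optional susceptibility-coupled perturbation model (cancer cohorts):
    # locus l carries susceptibility s_l ~ U(0,1)^2 (layout); a sample with
    # clone fraction f perturbs l with probability perturb_prob_max * s_l at
    # cell fraction f * (0.3 + 0.7 * s_l). Frequently hit loci are thereby
    # perturbed at larger cell fractions, coupling recurrence to the
    # conditional methylation level.
    coupled_perturbation: bool = False
    perturb_prob_max: float = 0.3

    # Age model: expected number of perturbed stable-low loci per sample is
    # age_locus_rate_per_year * (age - age_range[0]); perturbed loci carry a
    # small clone of fraction drawn from age_clone_fraction_range.
    age_range: tuple[float, float] = (18.0, 18.0)
    age_locus_rate_per_year: float = 0.0
    age_clone_fraction_range: tuple[float, float] = (0.05, 0.3)

    # Survival model (times in years).
    baseline_hazard: float = 0.05
    log_hr_high: float = float(np.log(1.5))
    censoring_rate: float = 0.2

    # The probe layout (which probes are stable, per-probe means of variable
    # probes) is a property of the genome, shared by every cohort simulated
    # from the same config; it has its own seed so cohorts with different
    # sampling seeds still agree on the planted structure.
    layout_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_samples <= 0:
            raise ValueError("n_probes and n_samples must be positive")
        for name in ("fraction_stable_unmeth", "fraction_stable_meth",
                     "clone_prevalence", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_stable_unmeth + self.fraction_stable_meth >= 1.0:
            raise ValueError("stable fractions must sum to < 1")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    @classmethod
    def aging_population(cls, **overrides) -> "SimulationConfig":
        """A non-cancer adult cohort in which instability accrues with age."""
        kw = dict(age_range=(20.0, 90.0), age_locus_rate_per_year=0.3)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def cancer_cohort(cls, **overrides) -> "SimulationConfig":
        """A malignant cohort: every sample carries an expanded epi-clone."""
        kw = dict(clone_prevalence=1.0, clone_fraction_range=(0.2, 0.95))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SimulationTruth:
    """Planted ground truth accompanying a simulated cohort."""

    stable_low: pd.Index
    stable_high: pd.Index
    variable: pd.Index
    signatures: dict[str, np.ndarray] = field(default_factory=dict)
    clone_fraction: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    groups: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def stable(self) -> pd.Index:
        return self.stable_low.union(self.stable_high)


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


@dataclass
class _Layout:
    """Genome layout shared by every cohort simulated from one config."""

    probe_ids: pd.Index
    low_pos: np.ndarray
    high_pos: np.ndarray
    var_pos: np.ndarray
    probe_means: np.ndarray  # per-probe expected β
    susceptibility: np.ndarray  # per-probe perturbation susceptibility in [0, 1]


def _probe_layout(cfg: SimulationConfig) -> _Layout:
    """Draw the layout from ``cfg.layout_seed`` only, so cohorts simulated
    with different sampling seeds still agree on the planted structure."""
    rng = np.random.default_rng(cfg.layout_seed)
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(cfg.n_probes)], name="probe_id")
    n_low = int(round(cfg.fraction_stable_unmeth * cfg.n_probes))
    n_high = int(round(cfg.fraction_stable_meth * cfg.n_probes))
    perm = rng.permutation(cfg.n_probes)
    low_pos = np.sort(perm[:n_low])
    high_pos = np.sort(perm[n_low:n_low + n_high])
    var_pos = np.sort(perm[n_low + n_high:])
    means = np.empty(cfg.n_probes)
    a, b = _beta_params(cfg.stable_low_mean, cfg.stable_mean_concentration)
    means[low_pos] = rng.beta(a, b, size=len(low_pos))
    a, b = _beta_params(cfg.stable_high_mean, cfg.stable_mean_concentration)
    means[high_pos] = rng.beta(a, b, size=len(high_pos))
    means[var_pos] = rng.uniform(*cfg.variable_mean_range, size=len(var_pos))
    susceptibility = rng.uniform(0.0, 1.0, size=cfg.n_probes) ** 2
    return _Layout(probe_ids, low_pos, high_pos, var_pos, means, susceptibility)


def _background(cfg: SimulationConfig, rng: np.random.Generator,
                layout: _Layout, n_samples: int) -> np.ndarray:
    m = layout.probe_means
    k = np.full(cfg.n_probes, cfg.variable_concentration)
    k[layout.low_pos] = cfg.stable_concentration
    k[layout.high_pos] = cfg.stable_concentration
    return rng.beta((m * k)[:, None], ((1.0 - m) * k)[:, None],
                    size=(cfg.n_probes, n_samples))


def _mix_clone(cfg: SimulationConfig, rng: np.random.Generator,
               vals: np.ndarray, loci: np.ndarray, col: int, f: float) -> None:
    """Overwrite ``vals[loci, col]`` with the (1−f)·bg + f·clone mixture."""
    if f <= 0 or len(loci) == 0:
        return
    a, b = _beta_params(cfg.clone_meth_mean, cfg.clone_meth_concentration)
    clone = rng.beta(a, b, size=len(loci))
    vals[loci, col] = (1.0 - f) * vals[loci, col] + f * clone


def simulate_cohort(
    config: SimulationConfig,
    seed: int,
    clone_fractions: np.ndarray | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, SimulationTruth]:
    """Simulate a cross-sectional cohort.

    ``clone_fractions`` overrides the config's clone prevalence/fraction
    model with an explicit per-sample clone cell fraction (0 = no clone);
    this is how dose–response experiments plant a known mixture series.

    Returns the β matrix, a sample-metadata table, and the planted truth.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    layout = _probe_layout(cfg)
    probe_ids, low_pos = layout.probe_ids, layout.low_pos
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    vals = _background(cfg, rng, layout, n)

    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)

    if clone_fractions is None:
        has_clone = rng.random(n) < cfg.clone_prevalence
        clone_fractions = np.where(
            has_clone, rng.uniform(*cfg.clone_fraction_range, size=n), 0.0
        )
    else:
        clone_fractions = np.asarray(clone_fractions, dtype=float)
        if clone_fractions.shape != (n,):
            raise ValueError("clone_fractions must have one entry per sample")

    signatures: dict[str, np.ndarray] = {}
    for j, sid in enumerate(sample_ids):
        f = clone_fractions[j]
        if f > 0 and cfg.coupled_perturbation:
            s = layout.susceptibility[low_pos]
            hit = rng.random(len(low_pos)) < cfg.perturb_prob_max * s
            loci = low_pos[hit]
            signatures[sid] = probe_ids[loci].to_numpy()
            a, b = _beta_params(cfg.clone_meth_mean, cfg.clone_meth_concentration)
            clone = rng.beta(a, b, size=len(loci))
            f_loc = f * (0.3 + 0.7 * layout.susceptibility[loci])
            vals[loci, j] = (1.0 - f_loc) * vals[loci, j] + f_loc * clone
        elif f > 0:
            loci = rng.choice(low_pos, size=cfg.signature_size, replace=False)
            signatures[sid] = probe_ids[loci].to_numpy()
            _mix_clone(cfg, rng, vals, loci, j, f)
        # age-accrued small clones, independent of the malignant signature
        if cfg.age_locus_rate_per_year > 0:
            lam = cfg.age_locus_rate_per_year * max(ages[j] - cfg.age_range[0], 0.0)
            n_pert = min(rng.poisson(lam), len(low_pos))
            if n_pert > 0:
                loci = rng.choice(low_pos, size=n_pert, replace=False)
                f_age = rng.uniform(*cfg.age_clone_fraction_range)
                _mix_clone(cfg, rng, vals, loci, j, f_age)

    matrix = BetaMatrix(pd.DataFrame(vals, index=probe_ids, columns=sample_ids))
    meta = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "cohort": "synthetic",
            "disease": np.where(clone_fractions > 0, "clone", "healthy"),
            "tissue": "whole_blood",
            "age": ages,
            "sex": rng.choice(["F", "M"], size=n),
            "timepoint": "none",
            "clone_vaf": clone_fractions / 2.0,  # heterozygous driver proxy
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimulationTruth(
        stable_low=probe_ids[low_pos],
        stable_high=probe_ids[layout.high_pos],
        variable=probe_ids[layout.var_pos],
        signatures=signatures,
        clone_fraction=pd.Series(clone_fractions, index=meta.index),
        groups=pd.Series(meta["disease"], index=meta.index),
    )
    return matrix, meta, truth


def simulate_longitudinal_cohort(
    config: SimulationConfig,
    n_patients: int,
    seed: int,
    relapse_factor: float = 1.0,
    include_remission: bool = True,
    disjoint_signatures: bool = True,
) -> tuple[BetaMatrix, pd.DataFrame, SimulationTruth]:
    """Simulate diagnosis/remission/relapse triplets sharing one epi-clone.

    Each patient carries one signature (``signature_size`` stable-low loci,
    disjoint across patients by default). Diagnosis clone fraction is drawn
    from the config range; relapse is diagnosis × ``relapse_factor`` clipped
    to 1; remission is clone-free.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = config
    layout = _probe_layout(cfg)
    probe_ids, low_pos = layout.probe_ids, layout.low_pos
    if disjoint_signatures and n_patients * cfg.signature_size > len(low_pos):
        raise ValueError("not enough stable-low probes for disjoint signatures")

    timepoints = ["diagnosis", "remission", "relapse"] if include_remission \
        else ["diagnosis", "relapse"]
    patients = [f"P{i:03d}" for i in range(n_patients)]
    sample_ids = [f"{p}_{tp}" for p in patients for tp in timepoints]
    n = len(sample_ids)
    vals = _background(cfg, rng, layout, n)

    if disjoint_signatures:
        pool = rng.permutation(low_pos)
        sig_pos = {p: np.sort(pool[i * cfg.signature_size:(i + 1) * cfg.signature_size])
                   for i, p in enumerate(patients)}
    else:
        sig_pos = {p: rng.choice(low_pos, size=cfg.signature_size, replace=False)
                   for p in patients}

    fractions, signatures = {}, {}
    f_dx_all = rng.uniform(*cfg.clone_fraction_range, size=n_patients)
    for i, p in enumerate(patients):
        f_dx = f_dx_all[i]
        per_tp = {"diagnosis": f_dx, "remission": 0.0,
                  "relapse": min(1.0, f_dx * relapse_factor)}
        for tp in timepoints:
            sid = f"{p}_{tp}"
            col = sample_ids.index(sid)
            f = per_tp[tp]
            fractions[sid] = f
            signatures[sid] = probe_ids[sig_pos[p]].to_numpy()
            _mix_clone(cfg, rng, vals, sig_pos[p], col, f)

    matrix = BetaMatrix(pd.DataFrame(vals, index=probe_ids, columns=sample_ids))
    meta = pd.DataFrame(
        {
            "patient_id": [s.rsplit("_", 1)[0] for s in sample_ids],
            "cohort": "synthetic_longitudinal",
            "disease": "leukemia",
            "tissue": "bone_marrow",
            "timepoint": [s.rsplit("_", 1)[1] for s in sample_ids],
            "clone_vaf": [fractions[s] / 2.0 for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimulationTruth(
        stable_low=probe_ids[low_pos],
        stable_high=probe_ids[layout.high_pos],
        variable=probe_ids[layout.var_pos],
        signatures=signatures,
        clone_fraction=pd.Series(fractions).reindex(meta.index),
        groups=pd.Series(meta["timepoint"], index=meta.index),
    )
    return matrix, meta, truth


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential-censoring rate giving an expected censored fraction ``target``.

    For T ~ Exp(h) and independent C ~ Exp(c), P(censored) = c / (c + h);
    the mean over samples is monotone in c, so a bracketed root finder
    recovers the rate exactly.
    """
    def expected(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = 1e-12, float(hazards.max())
    while expected(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for target < 1
            break
    return brentq(expected, lo, hi)


def simulate_survival_cohort(
    config: SimulationConfig,
    groups: pd.Series | np.ndarray,
    seed: int,
) -> pd.DataFrame:
    """Simulate event times under proportional hazards for labelled groups.

    ``groups`` holds "high"/"low" instability labels per sample. The high
    group's hazard is ``baseline_hazard * exp(log_hr_high)``. Censoring is
    independent exponential, with its rate solved so the expected censored
    fraction equals ``censoring_rate``; a rate of 1 yields zero events.
    """
    cfg = config
    groups = pd.Series(groups)
    if not groups.index.dtype == object:
        groups.index = [f"S{i:04d}" for i in range(len(groups))]
    is_high = (groups == "high").to_numpy()
    if not set(groups.unique()) <= {"high", "low"}:
        raise ValueError("groups must be labelled 'high' or 'low'")
    rng = np.random.default_rng(seed)
    hazards = cfg.baseline_hazard * np.exp(cfg.log_hr_high * is_high)
    event_times = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate >= 1.0:
        time, event = event_times, np.zeros(len(groups), dtype=int)
    elif cfg.censoring_rate <= 0.0:
        time, event = event_times, np.ones(len(groups), dtype=int)
    else:
        c = _solve_censoring_rate(hazards, cfg.censoring_rate)
        censor_times = rng.exponential(1.0 / c, size=len(groups))
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)
    return pd.DataFrame(
        {"time": time, "event": event, "group": groups.to_numpy(),
         "high": is_high.astype(int)},
        index=pd.Index(groups.index, name="sample_id"),
    )


def simulate_probe_annotation(
    probe_ids: pd.Index,
    esl_probes: pd.Index | None,
    seed: int,
    esl_island_prob: float = 0.8,
    background_island_prob: float = 0.2,
    esl_tss_scale: float = 500.0,
    background_tss_scale: float = 5000.0,
    flag_fraction: float = 0.0,
) -> pd.DataFrame:
    """Generate an annotation manifest with planted genomic-context structure.

    Probes in ``esl_probes`` receive island membership with probability
    ``esl_island_prob`` and TSS distances drawn tightly around the TSS
    (Laplace with scale ``esl_tss_scale``); background probes use the looser
    background parameters. ``flag_fraction`` marks a random subset with each
    blocklist flag, for exercising probe filtering.
    """
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    is_esl = probe_ids.isin(esl_probes) if esl_probes is not None \
        else np.zeros(n, dtype=bool)
    p_island = np.where(is_esl, esl_island_prob, background_island_prob)
    island = rng.random(n) < p_island
    other = rng.choice(["shore", "shelf", "open_sea"], size=n)
    cgi = np.where(island, "island", other)
    scale = np.where(is_esl, esl_tss_scale, background_tss_scale)
    tss = np.rint(rng.laplace(0.0, scale)).astype(int)
    ann = pd.DataFrame(
        {
            "chromosome": rng.choice([f"chr{i}" for i in range(1, 23)], size=n),
            "position": rng.integers(1, 2_000_000, size=n),
            "cgi_relation": cgi,
            "nearest_gene": [f"GENE{i % max(1, n // 3):05d}" for i in range(n)],
            "tss_distance": tss,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    from .core_io import BLOCKLIST_FLAGS
    for flag in BLOCKLIST_FLAGS:
        if flag == "sex_chromosome":
            ann[flag] = False  # chromosomes above are all autosomes
        else:
            ann[flag] = rng.random(n) < flag_fraction
    return ann


def simulate_expression_cohort(
    n_genes: int,
    n_planted: int,
    n_samples: int,
    seed: int,
    esls_per_gene: tuple[int, int] = (1, 3),
    perturb_prob_range: tuple[float, float] = (0.15, 0.5),
    meth_effect: float = 4.0,
    age_effect: float = 0.03,
    noise_sd: float = 0.3,
    age_range: tuple[float, float] = (20.0, 80.0),
    config: SimulationConfig | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, pd.Series, pd.DataFrame, pd.Index]:
    """Simulate promoter methylation, expression and age with planted silencing.

    Each gene owns 1–3 promoter loci (annotation places them within 1500 bp
    upstream of the TSS). For the ``n_planted`` silenced-with-age genes, the
    probability that a sample is perturbed at the gene's loci rises linearly
    with age, and log2 expression decreases with both promoter methylation
    (slope ``meth_effect``) and age (slope ``age_effect``). Null genes carry
    baseline noise only.

    Returns (β matrix, expression genes × samples, ages, annotation, planted
    gene index).
    """
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    cfg = config or SimulationConfig()
    genes = pd.Index([f"GENE{i:04d}" for i in range(n_genes)], name="gene")
    planted = genes[:n_planted]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    ages = pd.Series(rng.uniform(*age_range, size=n_samples),
                     index=pd.Index(samples, name="sample_id"), name="age")

    # gene/probe structure and per-probe means are genome properties: drawn
    # from the layout seed so cohorts simulated from the same config share
    # them (a calibration cohort must see the same probes as the analysis
    # cohort)
    layout_rng = np.random.default_rng(cfg.layout_seed + 7)
    n_esl = layout_rng.integers(esls_per_gene[0], esls_per_gene[1] + 1, size=n_genes)
    probe_ids, gene_of_probe = [], []
    for g, k in zip(genes, n_esl):
        for j in range(k):
            probe_ids.append(f"cg_{g}_{j}")
            gene_of_probe.append(g)
    probe_ids = pd.Index(probe_ids, name="probe_id")

    a, b = _beta_params(cfg.stable_low_mean, cfg.stable_mean_concentration)
    probe_means = layout_rng.beta(a, b, size=len(probe_ids))
    k = cfg.stable_concentration
    beta = rng.beta((probe_means * k)[:, None], ((1.0 - probe_means) * k)[:, None],
                    size=(len(probe_ids), n_samples))

    age_z = (ages.to_numpy() - age_range[0]) / (age_range[1] - age_range[0])
    perturb = np.zeros((n_genes, n_samples), dtype=bool)
    for gi, g in enumerate(genes):
        if g not in planted:
            continue
        base = rng.uniform(*perturb_prob_range)
        p = np.clip(base * (0.5 + age_z), 0.0, 1.0)
        perturb[gi] = rng.random(n_samples) < p
        rows = np.flatnonzero(np.asarray(gene_of_probe) == g)
        ca, cb = _beta_params(0.4, 30.0)
        for j in np.flatnonzero(perturb[gi]):
            f = rng.uniform(0.4, 0.9)
            clone = rng.beta(ca, cb, size=len(rows))
            beta[rows, j] = (1.0 - f) * beta[rows, j] + f * clone

    gene_meth = np.vstack([
        beta[np.flatnonzero(np.asarray(gene_of_probe) == g)].mean(axis=0)
        for g in genes
    ])
    base_expr = rng.uniform(3.0, 8.0, size=n_genes)
    expr = base_expr[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    planted_mask = genes.isin(planted)
    expr[planted_mask] -= meth_effect * gene_meth[planted_mask]
    expr[planted_mask] -= age_effect * (ages.to_numpy() - age_range[0])
    expr = np.maximum(expr, 0.0)
    # expression is delivered on a TPM-like linear scale
    expression = pd.DataFrame(np.expm1(expr * np.log(2)), index=genes, columns=samples)

    ann = simulate_probe_annotation(probe_ids, None, seed + 1)
    ann["nearest_gene"] = gene_of_probe
    ann["tss_distance"] = rng.integers(-1400, -20, size=len(probe_ids))
    ann["cgi_relation"] = "island"

    matrix = BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=samples))
    return matrix, expression, ages, ann, planted
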