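# epistab

Analysis of **epigenetically stable loci (ESLs)** and **DNA methylation
instability (DMI)** in blood methylomes.

Most CpG loci vary between healthy people, which makes it hard to call any
single methylation state "abnormal". A minority of loci, however, sit
tightly at one pole of the β-value scale (β = methylated signal fraction,
in [0, 1]) across young, healthy donors — stably unmethylated near 0 or
stably methylated near 1. Methylation appearing at a normally unmethylated
ESL behaves like a somatic, heritable mark of an expanded blood-cell clone:
it scales with clone fraction, persists from leukemia diagnosis to relapse,
accumulates with age, and stratifies cardiovascular risk and survival.
`epistab` implements the full analysis chain for researchers in
epigenomics and clonal hematopoiesis:

- **discovery** of ESLs from a healthy-cohort β matrix: blocklist
  filtering, variance ranking, least-variable-decile selection,
  purified-cell outlier refinement, bimodal classification;
- **calibration** of the destabilization threshold as the 99.9th percentile
  of per-cohort ESL means pooled across control cohorts;
- **binarization** of perturbation calls (β strictly above the threshold)
  and per-locus **recurrence** (< 5% low-recurrence, ≥ 5% recurrent), with
  the conditional mean β over affected samples;
- the per-sample **DMI** statistic — the standard deviation of a sample's
  β over a designated ESL subset — with longitudinal trajectories and
  5-year-binned age trends;
- **lineage enrichment** of perturbed loci between leukemia lineages by
  two-sided Fisher's exact tests with Bonferroni correction and
  odds-ratio/prevalence selection rules;
- **epi-clone matching** of diagnosis–relapse pairs: top-15 low-recurrence
  signature loci per patient, Ward clustering on 1 − Pearson r, and a
  permutation test drawing random signatures per patient;
- **outcome analysis**: median/quartile DMI stratification, Kaplan–Meier
  curves, log-rank tests, Cox proportional-hazards fits, and a
  simulation-based power/sample-size search;
- **gene prioritization** by three criteria: significant negative
  promoter-methylation–expression correlation, significant negative
  age–expression correlation, and mean promoter-ESL recurrence above 5%;
  plus CpG-island/TSS context enrichment.

A seeded synthetic-cohort generator (`epistab.simulate`) plants known
stable loci, patient-specific clonal signatures, age drift and
DMI-linked survival, so every stage is testable against ground truth.
See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import epistab as es

# 1. a young-healthy discovery cohort with 10% planted stable loci
cfg = es.SimulationConfig(n_probes=4000, n_samples=300)
matrix, meta, truth = es.simulate_cohort(cfg, seed=1)

# 2. discover epigenetically stable loci
esl = es.discover_esls(matrix, fraction=0.10)
unmeth = esl.index[esl["esl_class"] == "unmethylated"]

# 3. calibrate the destabilization threshold from three control cohorts
ctrl_cfg = es.SimulationConfig(n_probes=4000, n_samples=100)
controls = [es.simulate_cohort(ctrl_cfg, seed=s)[0].select_probes(unmeth)
            for s in (2, 3, 4)]
threshold = es.calibrate_threshold(controls, percentile=99.9)

# 4. binarize a leukemia cohort and score recurrence
cancer_cfg = es.SimulationConfig.cancer_cohort(
    n_probes=4000, n_samples=200, coupled_perturbation=True)
cancer, _, _ = es.simulate_cohort(cancer_cfg, seed=5)
calls = es.binarize(cancer.select_probes(unmeth), threshold)
rec = es.recurrence(calls)
cmb = es.conditional_mean_beta(cancer.select_probes(unmeth), calls)
r, p = es.recurrence_beta_correlation(rec["recurrence"], cmb)

# 5. per-sample instability over the recurrent subset
recurrent = rec.index[rec["recurrence_class"] == "recurrent"]
dmi_cancer = es.compute_dmi(cancer, recurrent)["dmi"]
dmi_healthy = es.compute_dmi(matrix, recurrent)["dmi"]

# 6. pair diagnosis and relapse samples by their epi-clone signatures
long_cfg = es.SimulationConfig(n_probes=4000, fraction_stable_unmeth=0.9,
                               fraction_stable_meth=0.02,
                               clone_fraction_range=(0.3, 0.9))
lmat, lmeta, ltruth = es.simulate_longitudinal_cohort(
    long_cfg, 24, seed=7, include_remission=False)
match = es.cluster_and_pair(lmat, lmeta, ltruth.stable_low, k=15)
perm = es.permutation_test(lmat, lmeta, match.n_correct, ltruth.stable_low,
                           k=15, n_sims=1000, seed=8)
```

Output:

```
ESLs discovered: 400 (320 unmethylated / 80 methylated)
destabilization threshold: 0.06325
recurrence classes: {'recurrent': 203, 'low': 117}
recurrence vs conditional mean beta: r = 0.77, p = 1.0e-56
median DMI: healthy 0.0127, leukemia 0.1242
diagnosis-relapse matching: 24/24 correct, permutation p = 0.029
```

Reading the numbers: the 400 discovered loci are exactly the planted
stable decile, split by pole. The calibrated threshold (β ≈ 0.063) sits in
the extreme upper tail of healthy ESL means, so healthy samples rarely
cross it while clonal perturbations do. Loci destabilized in more patients
also carry higher methylation among affected patients (r = 0.77) — the
hallmark of clone-borne, rather than random in-situ, methylation. DMI
separates leukemia from healthy samples by an order of magnitude, and the
15-locus epi-clone signatures pair all 24 diagnosis–relapse couples, far
beyond what random low-recurrence loci achieve.

A command-line interface mirrors the library
(`epistab simulate | discover-esl | calibrate | binarize | recurrence |
dmi | match | outcome | prioritize`); every subcommand takes `--config`
(YAML) and `--seed` and echoes its effective parameters.

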