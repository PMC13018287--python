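# Methods

## The model in brief

Blood methylomes measured on CpG arrays report, per locus, a β-value — the
fraction of methylated signal, in [0, 1]. Most loci vary between people;
a minority are *epigenetically stable loci* (ESLs), sitting tightly at one
pole (β ≈ 0, stably unmethylated, or β ≈ 1, stably methylated) across young,
healthy donors. Departures from an ESL's pole ("destabilization" or
"perturbation") behave like somatic, heritable marks of expanded blood-cell
clones, and their per-sample dispersion — the *DNA methylation instability*
statistic, DMI — tracks clonal burden, age and cardiovascular risk.

The package implements the full analysis chain:

1. **Discovery** — rank probes by cross-cohort β variance (unbiased, n−1
   denominator), keep the least-variable decile, optionally drop candidates
   with outlier β in purified cell types, and split the survivors at β = 0.5
   into unmethylated/methylated, refusing anything in the intermediate band.
2. **Calibration** — per healthy control cohort, compute the mean β of each
   unmethylated ESL; pool all cohort × locus means; the destabilization
   threshold is the 99.9th percentile of the pool (mirrored 0.1st percentile
   for the methylated pole).
3. **Binarization and recurrence** — a call of 1 at a low-pole ESL requires
   β strictly above the threshold; recurrence is the fraction of samples
   called per locus (missing calls leave both numerator and denominator);
   ≥ 5% is "recurrent", below is "low-recurrence".
4. **DMI** — the sample standard deviation (n−1) of a sample's β over a
   designated ESL subset, by default the recurrent class.
5. **Lineage enrichment** — per-locus two-sided Fisher's exact tests of
   perturbation counts between lineage groups, Bonferroni over loci, with
   odds-ratio/prevalence selection rules for lymphoid- and myeloid-enriched
   sets.
6. **Epi-clone matching** — per patient, the k = 15 low-recurrence loci with
   the highest β in the relapse sample; Ward clustering of all diagnosis +
   relapse samples on 1 − Pearson r over the union of signatures; a patient
   is correctly paired when its two samples merge as immediate dendrogram
   siblings; significance by permutation (k random pool loci per patient per
   simulation, p = proportion of simulations with count ≥ observed).
7. **Outcomes** — median or extreme-quartile DMI stratification,
   Kaplan–Meier curves with log-log CIs, log-rank tests, Cox
   proportional-hazards fits, and a simulation-based power/sample-size
   search.
8. **Gene prioritization** — map recurrently perturbed ESLs to promoters
   (upstream-only 1500 bp window), require a significant negative
   methylation–expression correlation, a significant negative
   age–expression correlation, and mean promoter-ESL recurrence above 5%;
   CpG-island/TSS context enrichment uses the symmetric ±1500 bp window and
   a raw cross-product odds ratio with Fisher's p.

## Numerical conventions

- **Percentile definition.** Linear interpolation between order statistics
  (numpy's "linear", the classic type-7 rule). The 99.9th percentile of a
  finite pool is definition-sensitive, so this is fixed and echoed in CLI
  output.
- **Strict threshold inequality.** "Exceeding the threshold" is strict;
  a β exactly at the threshold is not a call, making ties stable.
- **Tie-breaks.** Variance ranks, stable-set boundaries, top-k signatures
  and odds-ratio rankings all break ties lexicographically by probe ID
  (odds-ratio ranking first by smaller p), so every pipeline stage is
  deterministic across platforms.
- **Missing data.** Statistics use complete observations: variance and DMI
  drop missing values per probe/sample (minimum two observations, otherwise
  excluded with a warning); recurrence drops missing calls from both sides
  of the fraction.
- **Ward on correlation distances.** Ward linkage formally presumes squared
  Euclidean distances; running it on 1 − Pearson r is a pragmatic field
  convention adopted deliberately, and the mutual-nearest-neighbour pairing
  variant is available for sensitivity analysis.
- **Permutation p.** The quoted exceedance proportion is implemented
  verbatim (no +1 correction; a `plus_one` flag provides the standard
  (b+1)/(m+1) estimator). The proportion is one-tailed by definition even
  where two-sided language appears alongside it.
- **Odds ratios.** Raw cross-product ratio; the Haldane–Anscombe 0.5 is
  added to all cells only when a zero cell occurs, keeping rankings finite.
- **Cox/KM machinery** is delegated to lifelines; convergence failures
  (collinearity, zero events) surface as `ValueError` with diagnostics.
- **Round-trip fidelity.** Matrices are written at full repr precision and
  read with round-trip float parsing, so write→read is exact.

## The synthetic-data generator

The generator is test scaffolding shaped like the phenomena under study,
not a model of array chemistry. Design:

- **Genome layout as a config property.** Which probes are stable, each
  probe's mean, and each probe's perturbation susceptibility are drawn from
  a dedicated `layout_seed`, so every cohort simulated from one config
  shares the planted genome — a prerequisite for cross-cohort operations
  like threshold calibration. The per-call `seed` drives sampling noise,
  clone assignments and ages; identical seeds reproduce cohorts exactly.
- **Noise.** β-values are beta-distributed around per-probe means. Stable
  probes draw their means from a pole-hugging Beta (default mean 0.015,
  concentration 150; mirrored at the high pole) with per-value concentration
  300; variable probes draw means uniformly on (0.05, 0.95) with
  concentration 10. With these defaults the pooled-mean 99.9th percentile
  lands near β ≈ 0.06 — the scale reported for real control cohorts — and
  stable/variable variances are separated by more than an order of
  magnitude. A single shared stable mean would put the threshold just above
  it and let ordinary noise exceed it constantly; the spread is what makes
  threshold calibration meaningful.
- **Clones.** A sample with clone fraction f mixes background and clone
  distributions at its signature loci: β = (1−f)·β_bg + f·β_clone, with
  β_clone around 0.85. E[β] is affine in f, which grounds the DMI
  dose–response checks. Signatures are drawn from the stable-low pool
  (without replacement; disjoint across patients in longitudinal cohorts).
  An optional susceptibility-coupled mode perturbs locus l with probability
  proportional to a per-locus susceptibility and at a cell fraction that
  grows with it, planting the positive recurrence–conditional-β coupling
  seen in real pan-cancer cohorts.
- **Ageing.** The expected number of small perturbed clones per sample grows
  linearly with age (Poisson counts, small mixing fractions), planting a
  DMI–age trend.
- **Survival.** Exponential proportional hazards with a configurable log-HR
  for the high-DMI group; independent exponential censoring whose rate is
  solved numerically so the expected censored fraction equals the config
  value.
- **Expression cohorts.** Each gene owns 1–3 promoter loci. Planted
  silenced-with-age genes have perturbation probability rising with age and
  log2 expression decreasing in both promoter methylation and age; null
  genes carry noise only.

What the generator does *not* emulate: batch and platform effects,
cell-composition shifts, probe cross-hybridization, genotype effects, and
the long-range correlation structure of real methylomes. Passing tests
therefore demonstrate that the pipeline's logic recovers planted structure
under its stated assumptions, not that real cohorts will show the published
effect sizes.

## Validation experiments and problem sizes

The benchmark module (run by the test suite and the reproduction script)
uses these sizes, chosen to give tight Monte-Carlo error at desk scale:

- percentile calibration vs a sort-and-interpolate oracle on 1000 random
  pools (exact to 1e-12);
- discovery precision/recall on twenty 10,000-probe × 500-sample cohorts
  with 10% planted stable loci;
- mean DMI over 50 replicates per clone fraction on the 0–0.9 grid
  (Spearman ρ = 1);
- all-correct diagnosis–relapse pairing on one hundred 24-patient cohorts
  (15-locus signatures, clone fraction ≥ 0.3), and permutation-null
  calibration over 500 clone-free cohorts at 200 simulations each. Because
  the correct-pair count is discrete, uniformity is assessed on the
  tie-randomized probability integral transform of the observed count among
  its simulated exchangeable draws — the construction that is exactly
  uniform iff the test is calibrated — rather than on the raw, atom-laden
  p-values;
- exact-test agreement with hypergeometric enumeration over all 46,376
  tables of total size ≤ 30;
- false-positive control under permuted lineage labels across 200 datasets;
- Cox log-HR bias and CI coverage over 100 planted HR = 1.5 cohorts of
  n = 2000 at 20% censoring, plus monotonicity of the power search in n and
  in the hazard ratio;
- gene-screen precision/recall on planted silencing and the zero-discovery
  rate over fully-null replicates (500 genes).

## Known limitations

- The purified-cell outlier rule ("outlier" is not standardizable from
  first principles) defaults to explicit pole bounds (ceiling 0.1 / floor
  0.9) with a Tukey-fence alternative; both are parameter-explicit rather
  than attempts to reconstruct any particular historical filter.
- Blocklists (SNP-adjacent, cross-reactive, age-predictive probes) are
  user-supplied annotation flags; the package does not reconstruct array
  manifests.
- The power search returns grid points, not exact minimal n; the closed-form
  Schoenfeld count is provided as a cross-check.
- Published cohort-specific numbers (locus counts, thresholds, hazard
  ratios, matching counts) require the original controlled-access/GEO
  cohorts and are out of scope; validation here is property-based on
  planted synthetic truth.
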