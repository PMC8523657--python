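# Methods

This document records the model implemented by `adaptsnv`, the default
parameters and why they were chosen, the simulator's guarantees, and the
numerical decisions that affect reproducibility.

## 1. Adaptive-SNV model

### Within-host differential calling

Each host contributes a pair of SNV tables (baseline T0 and endpoint T1;
optionally a follow-up T2). At every position called in either table the
*effective allele* is the called ALT allele, or the reference base when the
position is uncalled. A **differential SNV** exists when the effective
allele changes between timepoints, and is keyed by

```
SnvKey = (genome_id, position, from_allele, to_allele)
```

Consequences of this definition:

- A variant present at both timepoints is silent (no change).
- A reversion (ALT at T0, uncalled at T1) is a change with
  `from=ALT, to=REF`.
- ALT→ALT changes at one position are a single key with both non-reference
  alleles.
- Two calls at the same position with different ALTs inside one table are
  rejected as conflicting (`ValueError`): inputs are consensus calls, one
  allele per position per sample.

Only single-base A/C/G/T substitutions are considered; indels and
multi-base records are dropped at parse time (multiallelic records are
split first).

### Quality gates

VCF records are filtered **inclusively** at `quality ≥ 60` and
`depth ≥ 100` (both configurable). Species-level inclusion uses mean
relative abundance strictly `> 0.005` across passed samples.

### Prevalence, null model, universality

Per study, a differential SNV is retained when its prevalence among
**probiotic-arm** hosts is `≥ prevalence_threshold` (default 0.5; 0.3
available as a permissive preset). Candidates observed as a differential
SNV in *any* control-arm host of *any* study are excluded
(`null_model="control-arm"`), removing changes attributable to ordinary
within-gut dynamics rather than the intervention. A candidate is
**adaptive** when it survives in at least `study_min` studies (default 3 —
half of the canonical six-study design; requiring independent recurrence in
three unrelated cohorts makes chance recurrence of host-private variation
negligible). Requesting the control-arm null model on a cohort without
control hosts raises an error rather than silently passing everything.

`position_only=True` relaxes matching to genomic position alone (ignoring
alleles); it is guaranteed at least as permissive as full-key matching and
is intended for cross-caller comparisons.

### Depth normalization

Raw per-sample SNV counts scale with sequencing effort, so burden
comparisons use `nSNV = raw_count / sequencing_depth_Gb`. Doubling depth
halves nSNV by construction (property-tested).

## 2. Codon annotation

- Translation uses NCBI table 11 (bacteria). Genes on the minus strand are
  reverse-complemented before codon extraction; the reported from/to codons
  are in the coding frame.
- N/S classification compares translated amino acids of the reference and
  alternate codons; premature stops are flagged `nonsense` and count as
  nonsynonymous.
- Substitution classes are collapsed onto a purine reference: when the
  from-allele is a pyrimidine (C/T) both alleles are complemented, giving
  six possible classes (`A>C, A>G, A>T, G>A, G>C, G>T`).
- Per-gene selection uses the count ratio `dN/dS = N/S`, defined only when
  `S > 0`. Interpretation thresholds: `< 0.25` purifying, `> 1` positive,
  otherwise intermediate. Percentages are rounded half-up to one decimal.

The package ships a 19-row cross-study example table
(`adaptsnv.io.load_table3_fixture`) used in the documentation and tests;
its annotation tallies are 14 coding / 5 noncoding, 6 synonymous,
9 distinct proteins and 4 collapsed substitution classes.

## 3. Heritability across phases

Given adaptive sets from an intervention phase (phase I) and a later
follow-up phase (phase II):

- **retained** = phase I ∩ phase II, **transient** = phase I \ phase II,
  and `retained_fraction = |retained| / |phase I|` (undefined for empty
  phase I).
- Protein-level Venn partitions the union of proteins hit by retained vs
  transient SNVs (noncoding entries excluded).
- A protein is **entirely inherited** when all of its SNVs are retained and
  it carries at least `min_snvs=2`; **transient** when it carries ≥ 2
  transient SNVs and none retained. The 2-SNV floor avoids classifying
  proteins on a single observation.

## 4. Statistics

Thin, validated wrappers over scipy/scikit-bio so that all results carry
explicit `(statistic, p_value, method, n_permutations, seed)` provenance:

- Shannon (natural log) and Simpson (Gini or inverse variant) alpha
  diversity; Bray–Curtis dissimilarity.
- Pearson/Spearman correlation.
- Wilcoxon rank-sum: the **exact** null distribution is used when the
  pooled sample size is ≤ 20 and tie-free, otherwise the normal
  approximation; the method string records which was used.
- PERMANOVA with `p = (1 + #{F* ≥ F_obs}) / (1 + n_permutations)`; the
  permutation stream is seeded, so results are reproducible. Null
  calibration is enforced by test: across repeated null datasets the
  p-values are uniform (Kolmogorov–Smirnov check). Note that with
  `n_permutations = m` the p-values live on the lattice `k/(m+1)`, so the
  KS statistic is quantized.

## 5. Simulator

`simulate_cohort(SimConfig, reference)` produces a multi-study cohort with
a machine-readable planted truth:

- **Reference**: random genome with non-overlapping, in-frame genes packed
  by multinomial gap sampling; written as FASTA + GFF3.
- **Planted adaptive SNVs** (`n_planted_adaptive=5`): each supported by
  `planted_study_support=3` studies; within each supporting study the
  carriers are the first `⌈prevalence × n_probiotic⌉` probiotic hosts, so
  detectability at the default thresholds is guaranteed by construction.
- **Control-shared SNVs** (`n_control_shared`): planted in both arms; the
  control-arm null model must remove them (tested).
- **Background SNVs**: host-private; each study draws from its own disjoint
  position pool (seeded with the planted positions) so that within a study
  no two hosts share a background SNV. Expected per-host count is
  `n_background_per_host + depth_snv_coupling × depth`, realized Poisson.
  Note the pools are disjoint only *within* a study: at permissive
  `study_min` settings background keys can recur across studies, which is
  deliberate — universality thresholds, not the simulator, must provide
  specificity.
- **Follow-up** (`followup=True`): a fraction `retained_fraction` of the
  planted SNVs (count rounded half-up) persists at T2, the rest revert.
- **Noise flag** (`noise_below_threshold=True`): injects calls failing the
  default quality/depth gates, exercising the parser filters.
- All emitted calls otherwise pass the default gates; qualities are
  uniform in [60, 222] and depths integer in [100, 1000).

Default problem size (6 studies × 10 hosts × 2–3 timepoints, 100 kb
genome, 200 background SNVs/host) keeps a full pipeline run under ~3 s
while leaving the detection problem non-trivial (~24 000 background calls
against 5 planted truths).

## 6. Numerical and reproducibility decisions

- All randomness flows from `numpy.random.default_rng([seed % 2^31, stream])`
  with a distinct stream constant per concern (reference, planting,
  background, noise), so adding one feature never perturbs another's draws.
- Pipeline stages derive seeds as `(seed × 1_000_003 + k) mod (2^31 − 1)`.
- Rounding is half-up (via `Decimal` for percentages, `floor(x+0.5)` for
  retained counts) to avoid Python's banker's rounding surprising exact
  tests.
- Two runs with the same seed produce byte-identical output files
  (tested), including across different output directories.

## 7. Known limitations

- Consensus-call model: allele frequencies within a sample are not modeled;
  a position is either called (one ALT) or not. Sweeps below the caller's
  consensus threshold are invisible.
- The null model is presence-based exclusion, not a statistical test; a
  single control-arm observation vetoes a candidate.
- Count-ratio dN/dS ignores site opportunity (numbers of possible N vs S
  sites per gene); it is a screening statistic, not an evolutionary rate
  estimate.
- The simulator plants point truths; it does not model linkage, strain
  replacement, or read-level error processes.
- Universality treats studies as exchangeable and independent; no
  weighting by cohort size or depth is applied.
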