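# adaptsnv

Meta-analysis toolkit for detecting **adaptive single-nucleotide variants
(SNVs)** in gut bacterial populations from longitudinal probiotic
intervention cohorts, with codon-level annotation, heritability analysis
across study phases, and community-level statistics.

When a probiotic strain colonizes a new gut, its population acquires
mutations. Some are sequencing noise or host-private drift; a few recur
independently across unrelated hosts and studies, which is the signature of
adaptation to the gut environment. `adaptsnv` implements that detection
logic end to end:

1. **Within-host differential calling** — for each host, compare the SNV
   table at baseline (T0) against the intervention endpoint (T1). A variant
   counts when the *effective allele* (the called ALT, or the reference base
   when no call exists) changes between timepoints, keyed by
   `(genome, position, from_allele, to_allele)`. Reversions to reference
   count as changes.
2. **Prevalence filter** — within each study, keep variants present in at
   least a fraction (default 0.5) of probiotic-arm hosts.
3. **Control-arm null model** — discard candidates that also appear as
   within-host changes in any control-arm host; those reflect processes
   unrelated to the intervention.
4. **Universality** — call a variant *adaptive* when it survives the above
   in at least `study_min` (default 3) independent studies.
5. **Annotation** — map each adaptive SNV to its codon (translation
   table 11, strand-aware), classify synonymous/nonsynonymous, collapse
   substitutions to purine-reference classes, and compute per-gene
   count-ratio dN/dS.
6. **Heritability** — partition intervention-phase SNVs into *retained*
   vs *transient* using a later follow-up phase (T2), with protein-level
   Venn summaries.
7. **Community statistics** — depth-normalized SNV burden
   (nSNV = raw count / Gb sequenced), alpha diversity, Bray–Curtis
   distances, rank-sum tests and PERMANOVA.

A fully seeded cohort **simulator** with a planted ground truth supports
validation of every stage.

## Quickstart (CLI)

```bash
# simulate a 6-study cohort with 5 planted adaptive SNVs
adaptsnv simulate --seed 42 --out sim/

# detect adaptive SNVs from the per-sample VCFs + metadata
adaptsnv detect --snv-dir sim/snv --metadata sim/metadata.tsv --out adaptive.tsv

# annotate them against the reference
adaptsnv annotate --adaptive adaptive.tsv --fasta sim/reference.fasta \
                  --gff sim/genes.gff3 --out annotation.tsv

# or run everything at once with a JSON run report
adaptsnv run --simulate --seed 42 --out results/
```

## Quickstart (library)

Detection recovers the planted truth exactly on a noisy default cohort
(60 hosts, ~200 host-private background SNVs each):

```python
from adaptsnv.adaptive import MetaConfig, run_meta_analysis
from adaptsnv.simulate import SimConfig, generate_reference, simulate_cohort

cfg = SimConfig(seed=42, n_planted_adaptive=3)
sim = simulate_cohort(cfg, generate_reference(cfg))
# meta: DataFrame(sample_id, study, host, timepoint, arm, sequencing_depth)
# tables: {sample_id: [SnvCall, ...]}
res = run_meta_analysis(meta, tables, MetaConfig())
for k in sorted(res.universal):
    print(k)
```

```text
SnvKey(genome_id='synthetic_genome', position=26111, from_allele='C', to_allele='T')
SnvKey(genome_id='synthetic_genome', position=63276, from_allele='T', to_allele='G')
SnvKey(genome_id='synthetic_genome', position=63799, from_allele='C', to_allele='T')
```

Annotation of the packaged 19-SNV cross-study example table:

```python
from adaptsnv.annotate import consequences_from_table, summarize_annotation
from adaptsnv.io import load_table3_fixture

summarize_annotation(consequences_from_table(load_table3_fixture()))
```

```text
{'n_total': 19, 'n_coding': 14, 'n_noncoding': 5, 'pct_coding': 73.7,
 'n_synonymous': 6, 'n_nonsynonymous': 8,
 'class_counts': {'A>C': 2, 'A>G': 6, 'G>A': 9, 'G>T': 2},
 'n_classes': 4, 'n_proteins': 9, ...}
```

## Repository layout

- `src/adaptsnv/` — the library: `simulate`, `io`, `adaptive`, `annotate`,
  `heritability`, `stats`, `pipeline`, `cli`.
- `analysis/` — numbered drivers (`01_simulate.py` … `05_community_stats.py`)
  that run the full workflow on a simulated cohort, writing to `results/`.
- `scripts/acceptance.py` — one-shot acceptance run (see below).
- `tests/` — pytest suite incl. `tests/test_acceptance.py`.
- `docs/methods.md` — model, parameter choices and limitations.

## Testing

```bash
python -m pytest -q tests/
```

The suite (~150 tests, ~12 s) covers oracle equivalences (brute-force
differential enumeration, exhaustive 576-pair codon classification),
property-based invariants (hypothesis), statistical calibration
(PERMANOVA null uniformity) and end-to-end planted-truth recovery across
ten seeds.
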