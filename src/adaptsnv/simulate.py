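"""Synthetic multi-study probiotic-intervention cohorts with a planted truth set.

The simulator emulates the structure of a longitudinal probiotic
meta-analysis: several independent studies, each with a probiotic arm and a
placebo-control arm, paired baseline (T0) / endpoint (T1) stool metagenomes
per host, and optionally a long-term follow-up phase (T2). It emits the
same tabular artifacts the real pipeline consumes — a reference genome
(FASTA), gene models (GFF3), per-sample SNV call tables (VCF subset),
sample metadata and species relative-abundance tables (TSV) — plus a JSON
truth set recording exactly which variants were planted where, so every
downstream stage can be validated by parameter recovery.

Three variant populations are planted:

* **adaptive SNVs** — baseline→endpoint allele changes shared by a fixed
  fraction of probiotic-arm hosts in a configurable number of studies;
* **control-shared SNVs** — planted symmetrically in probiotic *and*
  control arms, so the control-arm null model has true positives to remove;
* **background SNVs** — host-private noise variants whose expected
  per-sample count rises linearly with sequencing depth, reproducing the
  depth/SNV-count coupling seen in real cohorts.

No reads are simulated; calls are consensus-style (one allele per host,
position and timepoint), matching the tabular level at which the detection
method operates.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

BASES = np.array(list("ACGT"))

#: default per-sample sequencing depth range in Gb, spanning the
#: average target depths reported for published probiotic cohorts
DEFAULT_DEPTH_RANGE = (1.2, 7.5)

_PRODUCT_POOL = [
    "ABC transporter permease",
    "carbohydrate ABC transporter substrate-binding protein",
    "sensor histidine kinase",
    "nitroreductase family protein",
    "A-type flavoprotein",
    "ribosomal protein",
    "ferritin-like protein",
    "phosphohydrolase",
    "peptidase",
    "toxin-antitoxin system toxin",
    "glycoside hydrolase",
    "two-component response regulator",
    "acyltransferase",
    "MFS transporter",
    "cell wall hydrolase",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally infeasible."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene model; 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Reference:
    """A reference genome plus its gene models."""

    genome_id: str
    sequence: str
    genes: list[Gene]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort scenario.

    Defaults mirror the meta-analysis design the pipeline targets: six
    independent paired-design studies, two arms, planted universal SNVs
    carried by 60% of probiotic hosts in three of six studies, and
    per-sample sequencing depths in the 1.2-7.5 Gb range typical of
    published probiotic shotgun cohorts.
    """

    seed: int = 0
    n_studies: int = 6
    hosts_per_study: int = 10
    control_fraction: float = 0.5
    genome_length: int = 100_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (300, 1500)
    n_planted_adaptive: int = 5
    planted_prevalence: float = 0.6
    planted_study_support: int = 3
    n_background_per_host: int = 200
    n_control_shared: int = 0
    depth_range: tuple[float, float] = DEFAULT_DEPTH_RANGE
    depth_snv_coupling: float = 0.0
    followup: bool = False
    retained_fraction: float = 0.5
    noise_below_threshold: bool = False
    genome_id: str = "synthetic_genome"

    def __post_init__(self) -> None:
        if min(self.n_studies, self.hosts_per_study, self.n_genes,
               self.n_planted_adaptive, self.n_background_per_host,
               self.n_control_shared) < 0:
            raise ConfigurationError("all counts must be >= 0")
        if not (0.0 <= self.control_fraction <= 1.0):
            raise ConfigurationError("control_fraction must be in [0, 1]")
        if not (0.0 <= self.planted_prevalence <= 1.0):
            raise ConfigurationError("planted_prevalence must be in [0, 1]")
        if not (0.0 <= self.retained_fraction <= 1.0):
            raise ConfigurationError("retained_fraction must be in [0, 1]")
        if self.planted_study_support > self.n_studies:
            raise ConfigurationError(
                "planted_study_support exceeds n_studies")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigurationError("depth_range must be positive and ordered")
        if self.depth_snv_coupling < 0:
            raise ConfigurationError("depth_snv_coupling must be >= 0")


@dataclass(frozen=True)
class PlantedSnv:
    """One planted variant: reference→alternate change plus where it was planted."""

    position: int
    ref_allele: str
    alt_allele: str
    studies: tuple[str, ...]


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort (used by recovery tests)."""

    planted_adaptive: list[PlantedSnv]
    control_shared: list[PlantedSnv]
    retained_at_T2: list[PlantedSnv] = field(default_factory=list)
    transient_at_T2: list[PlantedSnv] = field(default_factory=list)

    def adaptive_keys(self, genome_id: str) -> set[tuple]:
        return {(genome_id, p.position, p.ref_allele, p.alt_allele)
                for p in self.planted_adaptive}

    def to_json(self) -> str:
        def enc(items):
            return [dataclasses.asdict(p) for p in items]
        return json.dumps(
            {"planted_adaptive": enc(self.planted_adaptive),
             "control_shared": enc(self.control_shared),
             "retained_at_T2": enc(self.retained_at_T2),
             "transient_at_T2": enc(self.transient_at_T2)},
            indent=2, sort_keys=True)


@dataclass
class SimSample:
    sample_id: str
    study: str
    host: str
    arm: str  # 'probiotic' | 'control'
    timepoint: str  # 'T0' | 'T1' | 'T2'
    sequencing_depth: float


@dataclass
class SimCall:
    """A consensus-style SNV call emitted for one sample."""

    position: int
    ref_allele: str
    alt_allele: str
    quality: float
    depth: int


@dataclass
class CohortSim:
    """A fully materialized synthetic scenario."""

    config: SimConfig
    reference: Reference
    samples: list[SimSample]
    snv_tables: dict[str, list[SimCall]]  # sample_id -> calls
    abundance: "pd.DataFrame"  # taxon rows x sample columns
    truth: TruthSet


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic streams derived from the scenario seed
    return np.random.default_rng([int(seed) % (2**31), stream])


def generate_reference(config: SimConfig) -> Reference:
    """Build a random genome and a non-overlapping set of gene models.

    Gene lengths are multiples of 3 drawn from ``gene_length_range``;
    strands are random, product names distinct. Deterministic for a fixed
    ``config.seed``.
    """
    if config.genome_length < 1000:
        raise ConfigurationError("genome_length must be >= 1000")
    rng = _rng(config.seed, 0)
    seq = "".join(rng.choice(BASES, size=config.genome_length))

    genes: list[Gene] = []
    if config.n_genes > 0:
        lo, hi = config.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=config.n_genes)
        lengths = np.maximum(3, lengths - lengths % 3)
        total = int(lengths.sum())
        spare = config.genome_length - total
        if spare < 0:
            raise ConfigurationError(
                f"total gene length {total} exceeds genome length "
                f"{config.genome_length}")
        # distribute spare bases as inter-gene gaps
        gaps = rng.multinomial(spare, [1.0 / (config.n_genes + 1)]
                               * (config.n_genes + 1))
        pos = 1
        for i, length in enumerate(lengths):
            pos += int(gaps[i])
            strand = "+" if rng.random() < 0.5 else "-"
            product = (f"{_PRODUCT_POOL[i % len(_PRODUCT_POOL)]} "
                       f"{i // len(_PRODUCT_POOL) + 1}")
            genes.append(Gene(name=f"gene_{i + 1:04d}", start=pos,
                              end=pos + int(length) - 1, strand=strand,
                              product=product))
            pos += int(length)
    return Reference(genome_id=config.genome_id, sequence=seq, genes=genes)


def _plant_variants(rng, config, reference, n_variants, study_names,
                    forbidden: set[int]) -> list[PlantedSnv]:
    seq = reference.sequence
    planted = []
    for _ in range(n_variants):
        while True:
            pos = int(rng.integers(1, config.genome_length + 1))
            if pos not in forbidden:
                break
        forbidden.add(pos)
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        studies = tuple(sorted(
            rng.choice(study_names, size=config.planted_study_support,
                       replace=False)))
        planted.append(PlantedSnv(pos, ref, alt, studies))
    return planted


def simulate_cohort(config: SimConfig, reference: Reference) -> CohortSim:
    """Emit the full synthetic cohort for a reference genome.

    Planted adaptive SNVs appear as a T0→T1 allele change in exactly
    ``ceil(planted_prevalence x n_probiotic_hosts)`` probiotic-arm hosts of
    each supporting study, and never in control hosts. Control-shared SNVs
    are planted in both arms with the same prevalence rule so the null
    model has something to remove. Background SNVs are host-private
    (positions disjoint across hosts within a study and from all planted
    positions), with expected per-sample count
    ``n_background_per_host + depth_snv_coupling x depth``.
    """
    import pandas as pd

    rng = _rng(config.seed, 1)
    study_names = [f"study{i + 1:02d}" for i in range(config.n_studies)]
    n_control = int(round(config.control_fraction * config.hosts_per_study))
    n_prob = config.hosts_per_study - n_control

    if config.n_planted_adaptive > 0 or config.n_control_shared > 0:
        if n_prob > 0 and math.ceil(config.planted_prevalence * n_prob) == 0:
            raise ConfigurationError(
                "planted_prevalence rounds to 0 carrier hosts; "
                "planted SNVs would be undetectable")
        if n_prob == 0:
            raise ConfigurationError(
                "cannot plant adaptive SNVs without probiotic-arm hosts")

    forbidden: set[int] = set()
    planted = _plant_variants(rng, config, reference,
                              config.n_planted_adaptive, study_names,
                              forbidden)
    control_shared = _plant_variants(rng, config, reference,
                                     config.n_control_shared, study_names,
                                     forbidden)

    # half-up so retained_fraction=0.5 keeps the larger half for odd counts
    n_retained = math.floor(config.retained_fraction * len(planted) + 0.5)
    if config.followup and planted:
        order = rng.permutation(len(planted))
        retained = [planted[i] for i in sorted(order[:n_retained])]
        transient = [planted[i] for i in sorted(order[n_retained:])]
    else:
        retained, transient = [], []
    retained_set = {p.position for p in retained}

    timepoints = ["T0", "T1"] + (["T2"] if config.followup else [])
    samples: list[SimSample] = []
    snv_tables: dict[str, list[SimCall]] = {}

    def call(pos: int, ref: str, alt: str) -> SimCall:
        return SimCall(position=pos, ref_allele=ref, alt_allele=alt,
                       quality=round(float(rng.uniform(60.0, 222.0)), 1),
                       depth=int(rng.integers(100, 1000)))

    for study in study_names:
        used_positions: set[int] = set(forbidden)  # per-study privacy pool
        for j in range(config.hosts_per_study):
            arm = "control" if j < n_control else "probiotic"
            host = f"{study}_h{j + 1:02d}"
            # which planted variants does this host carry?
            carried: list[PlantedSnv] = []
            for group, eligible_arm in ((planted, "probiotic"),
                                        (control_shared, None)):
                for p in group:
                    if study not in p.studies:
                        continue
                    if eligible_arm is not None and arm != eligible_arm:
                        continue
                    pool = n_prob if arm == "probiotic" else n_control
                    rank = (j - n_control) if arm == "probiotic" else j
                    k = min(pool, math.ceil(config.planted_prevalence * pool))
                    k = max(k, 1)
                    if rank < k:
                        carried.append(p)
            for tp in timepoints:
                sample_id = f"{host}_{tp}"
                depth = float(rng.uniform(*config.depth_range))
                samples.append(SimSample(sample_id, study, host, arm, tp,
                                         round(depth, 3)))
                calls: list[SimCall] = []
                if tp != "T0":
                    for p in carried:
                        if (tp == "T2" and p in planted
                                and p.position not in retained_set):
                            continue  # transient: reverted by follow-up
                        calls.append(call(p.position, p.ref_allele,
                                          p.alt_allele))
                # host-private background noise, coupled to depth
                lam = (config.n_background_per_host
                       + config.depth_snv_coupling * depth)
                n_bg = int(rng.poisson(lam))
                for _ in range(n_bg):
                    while True:
                        pos = int(rng.integers(1, config.genome_length + 1))
                        if pos not in used_positions:
                            break
                    used_positions.add(pos)
                    ref = reference.sequence[pos - 1]
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                    calls.append(call(pos, ref, alt))
                if config.noise_below_threshold:
                    for _ in range(3):
                        while True:
                            pos = int(rng.integers(1, config.genome_length + 1))
                            if pos not in used_positions:
                                break
                        used_positions.add(pos)
                        ref = reference.sequence[pos - 1]
                        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                        sub = call(pos, ref, alt)
                        if rng.random() < 0.5:
                            sub.quality = round(float(rng.uniform(0, 59.9)), 1)
                        else:
                            sub.depth = int(rng.integers(1, 100))
                        calls.append(sub)
                calls.sort(key=lambda c: c.position)
                snv_tables[sample_id] = calls

    # species abundance table: focal species well above the 0.5% rule,
    # a few satellite taxa filling part of the remainder
    taxa = [reference.genome_id, "Eubacterium rectale",
            "Roseburia intestinalis", "Bacteroides uniformis",
            "Bifidobacterium longum"]
    ab = {}
    for s in samples:
        focal = rng.uniform(0.02, 0.15)
        rest = rng.dirichlet(np.ones(len(taxa) - 1)) * rng.uniform(0.4, 0.8)
        ab[s.sample_id] = np.concatenate([[focal], rest])
    abundance = pd.DataFrame(ab, index=taxa).round(6)
    abundance.index.name = "taxon"

    truth = TruthSet(planted_adaptive=planted, control_shared=control_shared,
                     retained_at_T2=retained, transient_at_T2=transient)
    return CohortSim(config=config, reference=reference, samples=samples,
                     snv_tables=snv_tables, abundance=abundance, truth=truth)


# ---------------------------------------------------------------------------
# file emission

def write_reference(reference: Reference, fasta_path: str, gff_path: str) -> None:
    """Write the genome as FASTA and its gene models as GFF3."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(reference.sequence), id=reference.genome_id,
                    description="synthetic reference genome")
    SeqIO.write([rec], fasta_path, "fasta")

    lines = ["##gff-version 3",
             f"##sequence-region {reference.genome_id} 1 "
             f"{len(reference.sequence)}"]
    for g in reference.genes:
        attrs = f"ID={g.name};product={g.product}"
        lines.append("\t".join([reference.genome_id, "adaptsnv_sim", "CDS",
                                str(g.start), str(g.end), ".", g.strand,
                                "0", attrs]))
    with open(gff_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_cohort(sim: CohortSim, outdir: str) -> dict[str, str]:
    """Materialize a simulated cohort under ``outdir``.

    Returns a dict of the paths written: reference FASTA/GFF3, one VCF per
    sample under ``snv/``, metadata.tsv, abundance.tsv and truth.json.
    """
    import pandas as pd

    from adaptsnv.io import write_snv_table

    os.makedirs(outdir, exist_ok=True)
    snv_dir = os.path.join(outdir, "snv")
    os.makedirs(snv_dir, exist_ok=True)

    paths = {"fasta": os.path.join(outdir, "reference.fasta"),
             "gff": os.path.join(outdir, "genes.gff3"),
             "metadata": os.path.join(outdir, "metadata.tsv"),
             "abundance": os.path.join(outdir, "abundance.tsv"),
             "truth": os.path.join(outdir, "truth.json"),
             "snv_dir": snv_dir}
    write_reference(sim.reference, paths["fasta"], paths["gff"])

    meta = pd.DataFrame([dataclasses.asdict(s) for s in sim.samples])
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    sim.abundance.to_csv(paths["abundance"], sep="\t")
    with open(paths["truth"], "w") as fh:
        fh.write(sim.truth.to_json() + "\n")

    for sample_id, calls in sim.snv_tables.items():
        write_snv_table(os.path.join(snv_dir, f"{sample_id}.vcf"),
                        sim.reference.genome_id, len(sim.reference.sequence),
                        calls)
    return paths
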