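"""Readers/writers for the pipeline's external formats, plus the pre-filters.

Formats: a VCF v4.2 subset for per-sample SNV calls (CHROM, POS, REF, ALT,
QUAL, INFO/DP; no FORMAT/sample columns required), GFF3 gene models, FASTA
reference genomes, and TSV metadata / species-abundance tables.

Two pre-filters gate everything downstream: calls must reach a minimum
quality (default 60) and read depth (default 100), both inclusive, and a
species enters SNV profiling only when its mean relative abundance in a
study strictly exceeds a threshold (default 0.5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_QUALITY_MIN = 60.0
DEFAULT_DEPTH_MIN = 100
DEFAULT_ABUNDANCE_MIN = 0.005


class SnvParseError(ValueError):
    """Raised when an SNV call table cannot be parsed."""


@dataclass(frozen=True)
class SnvCall:
    """One called variant in one sample."""

    genome_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    quality: float
    depth: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata joining a sample to its study, host, arm and timepoint."""

    sample_id: str
    study: str
    host: str
    arm: str  # 'probiotic' | 'control'
    timepoint: str  # 'T0' | 'T1' | 'T2'
    sequencing_depth: float  # Gb


# ---------------------------------------------------------------------------
# VCF subset

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=adaptsnv
##contig=<ID={genome_id},length={length}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snv_table(path: str, genome_id: str, genome_length: int,
                    calls) -> None:
    """Write calls as a minimal VCF v4.2 file (QUAL + INFO/DP only)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(genome_id=genome_id,
                                    length=genome_length))
        for c in calls:
            fh.write(f"{genome_id}\t{c.position}\t.\t{c.ref_allele}\t"
                     f"{c.alt_allele}\t{c.quality:g}\t.\tDP={c.depth}\n")


def _locate_malformed_line(path: str) -> int | None:
    """Best-effort scan for the first malformed data line (for error text)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                return lineno
            try:
                int(fields[1])
            except ValueError:
                return lineno
    return None


def read_snv_table(path: str, quality_min: float = DEFAULT_QUALITY_MIN,
                   depth_min: int = DEFAULT_DEPTH_MIN,
                   sample_id: str | None = None) -> list[SnvCall]:
    """Read one per-sample VCF, returning only calls that pass the filters.

    A record is kept when quality >= ``quality_min`` AND depth >=
    ``depth_min`` AND both REF and ALT are single bases (the pipeline
    analyzes SNVs only; indels are dropped). Multi-allelic records are
    split into one call per ALT before filtering. Counts of dropped
    records are logged.
    """
    import pysam

    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].removesuffix(".vcf")
    calls: list[SnvCall] = []
    n_dropped_filter = 0
    n_dropped_nonsnv = 0
    try:
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                depth = int(rec.info.get("DP", 0))
                qual = float(rec.qual) if rec.qual is not None else 0.0
                for alt in (rec.alts or ()):
                    if len(rec.ref) != 1 or len(alt) != 1 or \
                            rec.ref not in "ACGT" or alt not in "ACGT":
                        n_dropped_nonsnv += 1
                        continue
                    if qual < quality_min or depth < depth_min:
                        n_dropped_filter += 1
                        continue
                    calls.append(SnvCall(genome_id=rec.chrom, position=rec.pos,
                                         ref_allele=rec.ref, alt_allele=alt,
                                         quality=qual, depth=depth,
                                         sample_id=sample_id))
    except (ValueError, OSError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        lineno = _locate_malformed_line(path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise SnvParseError(f"malformed SNV table {path}{where}: {exc}") from exc
    if n_dropped_filter or n_dropped_nonsnv:
        logger.info("%s: dropped %d records below quality/depth thresholds "
                    "and %d non-SNV records", path, n_dropped_filter,
                    n_dropped_nonsnv)
    return calls


# ---------------------------------------------------------------------------
# reference + gene models

def read_reference_fasta(path: str) -> tuple[str, str]:
    """Return ``(genome_id, sequence)`` of the first FASTA record."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, str(rec.seq).upper()


def read_gene_models(path: str):
    """Read gene models from GFF3 (CDS/gene features with a product attribute)."""
    import gffutils

    from adaptsnv.simulate import Gene

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[Gene] = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        product = feat.attributes.get("product", ["NA"])[0]
        name = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(name=name, start=feat.start, end=feat.end,
                          strand=feat.strand, product=product))
    genes.sort(key=lambda g: g.start)
    return genes


# ---------------------------------------------------------------------------
# metadata / abundance

def read_metadata(path: str) -> pd.DataFrame:
    """Read the sample metadata TSV; validates uniqueness of (study, host, timepoint)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study": str,
                                              "host": str})
    required = {"sample_id", "study", "host", "arm", "timepoint",
                "sequencing_depth"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    dup = meta.duplicated(subset=["study", "host", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (study, host, timepoint) rows in metadata")
    return meta


def read_abundance(path: str) -> pd.DataFrame:
    """Read a taxon x sample relative-abundance TSV (fractions)."""
    ab = pd.read_csv(path, sep="\t", index_col=0)
    sums = ab.sum(axis=0)
    if (sums > 1 + 1e-6).any():
        raise ValueError("per-sample abundances sum to > 1")
    return ab


def select_species(abundance: pd.DataFrame,
                   threshold: float = DEFAULT_ABUNDANCE_MIN) -> list[str]:
    """Taxa whose mean relative abundance across samples strictly exceeds ``threshold``.

    The mean is taken over all samples passed in (call per study to apply
    the rule study-by-study). The comparison is strict, reflecting the
    "greater than 0.5%" convention.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if abundance.empty:
        raise ValueError("abundance table is empty")
    means = abundance.mean(axis=1)
    return list(means.index[means > threshold])


# ---------------------------------------------------------------------------
# packaged worked-example fixture

def load_table3_fixture() -> pd.DataFrame:
    """The 19 cross-study *F. prausnitzii* SNVs used as a worked example.

    Columns: position, gene_order, ref_base, alt_base, ref_codon,
    alt_codon, ref_aa, alt_aa, mutation_type ('N'/'S'/'noncoding'),
    protein (NaN when non-coding). Codons are canonicalized to the DNA
    alphabet (U -> T); the source prints a mix of DNA and RNA codons.
    """
    with resources.files("adaptsnv.data").joinpath("table3_snvs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    for col in ("ref_codon", "alt_codon"):
        df[col] = df[col].str.replace("U", "T")
    return df


def table3_keys(genome_id: str = "F_prausnitzii_ATCC27768"):
    """The fixture rows as SNV keys (genome, position, ref->alt)."""
    from adaptsnv.adaptive import SnvKey

    df = load_table3_fixture()
    return [SnvKey(genome_id, int(r.position), r.ref_base, r.alt_base)
            for r in df.itertuples()]
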