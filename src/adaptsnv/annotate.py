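"""Codon-level functional annotation of adaptive SNVs and per-gene selection.

Each SNV key is mapped onto the gene models: if it falls inside a coding
gene, the reference and alternate codons are reconstructed in the gene's
reading frame (alleles are complemented for minus-strand genes), both are
translated under the bacterial genetic code (NCBI table 11 by default),
and the change is typed synonymous (S) or non-synonymous (N). Substitution
classes are collapsed to a purine-reference representation (complementing
C/T-reference changes), giving six possible classes: A>G, A>C, A>T, G>A,
G>T, G>C.

Per-gene selection is summarized with a count-ratio dN/dS (pN/pS): the
ratio of non-synonymous to synonymous SNV counts in the gene, defined only
when the gene carries at least one synonymous change. Following the usual
reading for within-species polymorphism data, dN/dS < 0.25 is called
purifying and > 1 positive selection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio.Data import CodonTable
from Bio.Seq import Seq

from adaptsnv.adaptive import SnvKey

DEFAULT_CODON_TABLE = 11  # bacterial
DNDS_LOW = 0.25
DNDS_HIGH = 1.0

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(ValueError):
    """Raised when a gene model cannot be annotated consistently."""


@dataclass(frozen=True)
class CodonConsequence:
    """The codon-level consequence of one SNV."""

    key: SnvKey
    gene: str | None
    strand: str | None
    codon_index: int | None  # 1-based within the gene
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    mutation_type: str  # 'N' | 'S' | 'noncoding'
    protein: str | None
    collapsed_class: str
    nonsense: bool = False


@dataclass(frozen=True)
class GeneSelection:
    """Per-gene N/S tallies and the resulting selection call."""

    gene: str
    protein: str | None
    n_count: int
    s_count: int
    dnds: float | None
    selection_class: str  # 'purifying' | 'neutral-range' | 'positive' | 'undefined'


def _translate(codon: str, table: int) -> str:
    return str(Seq(codon).translate(table=table))


def classify_ns(ref_codon: str, alt_codon: str,
                table: int = DEFAULT_CODON_TABLE) -> str:
    """'S' when the two codons translate identically, else 'N'.

    The codons must differ at exactly one position; changes to or from a
    stop codon are classified N.
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise ValueError("codons must have length 3")
    diffs = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if diffs == 0:
        raise ValueError("codons are identical")
    if diffs > 1:
        raise ValueError("codons differ at more than one position")
    for c in ref_codon + alt_codon:
        if c not in "ACGT":
            raise ValueError(f"ambiguous or non-DNA base {c!r}")
    return "S" if _translate(ref_codon, table) == _translate(alt_codon, table) \
        else "N"


def collapse_class(key_or_from, to_allele: str | None = None) -> str:
    """Collapse a substitution to its purine-reference class.

    When the from-allele is a pyrimidine (C or T), both alleles are
    complemented, so the reported class always has A or G on the left;
    exactly six classes are possible.
    """
    if to_allele is None:
        frm, to = key_or_from.from_allele, key_or_from.to_allele
    else:
        frm, to = key_or_from, to_allele
    frm, to = frm.upper(), to.upper()
    if frm in "CT":
        frm, to = frm.translate(_COMPLEMENT), to.translate(_COMPLEMENT)
    return f"{frm}>{to}"


def map_to_codon(key: SnvKey, genes, genome: str,
                 table: int = DEFAULT_CODON_TABLE) -> CodonConsequence:
    """Annotate one SNV key against gene models and the genome sequence.

    For a minus-strand gene the coding sequence is the reverse complement
    of the genomic span, so both the codon context and the substituted
    alleles are complemented. Positions outside every gene are typed
    'noncoding'.
    """
    if not (1 <= key.position <= len(genome)):
        raise AnnotationError(
            f"position {key.position} outside the genome (length {len(genome)})")
    gene = next((g for g in genes if g.start <= key.position <= g.end), None)
    cclass = collapse_class(key)
    if gene is None:
        return CodonConsequence(key=key, gene=None, strand=None,
                                codon_index=None, ref_codon=None,
                                alt_codon=None, ref_aa=None, alt_aa=None,
                                mutation_type="noncoding", protein=None,
                                collapsed_class=cclass)
    if gene.length % 3 != 0:
        raise AnnotationError(
            f"gene {gene.name} has length {gene.length}, not divisible by 3")

    if gene.strand == "+":
        offset = key.position - gene.start
        frm, to = key.from_allele, key.to_allele
        cds_ctx = genome[gene.start - 1:gene.end]
    else:
        offset = gene.end - key.position
        frm = key.from_allele.translate(_COMPLEMENT)
        to = key.to_allele.translate(_COMPLEMENT)
        cds_ctx = genome[gene.start - 1:gene.end][::-1].translate(_COMPLEMENT)

    codon_index = offset // 3 + 1
    within = offset % 3
    codon = list(cds_ctx[3 * (codon_index - 1):3 * codon_index])
    ref_codon = codon.copy()
    ref_codon[within] = frm
    alt_codon = codon.copy()
    alt_codon[within] = to
    ref_codon, alt_codon = "".join(ref_codon), "".join(alt_codon)
    ref_aa = _translate(ref_codon, table)
    alt_aa = _translate(alt_codon, table)
    mtype = "S" if ref_aa == alt_aa else "N"
    return CodonConsequence(key=key, gene=gene.name, strand=gene.strand,
                            codon_index=codon_index, ref_codon=ref_codon,
                            alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
                            mutation_type=mtype, protein=gene.product,
                            collapsed_class=cclass,
                            nonsense="*" in (ref_aa, alt_aa))


def gene_dnds(consequences, low: float = DNDS_LOW,
              high: float = DNDS_HIGH) -> list[GeneSelection]:
    """Per-gene dN/dS from annotated consequences (non-coding rows ignored).

    dN/dS is the raw ratio of N to S counts, defined only when the gene
    has at least one synonymous SNV; with no synonymous changes the ratio
    (and the selection class) is undefined.
    """
    per_gene: dict[str, dict] = {}
    for c in consequences:
        if c.mutation_type not in ("N", "S") or c.gene is None:
            continue
        g = per_gene.setdefault(c.gene, {"protein": c.protein, "N": 0, "S": 0})
        g[c.mutation_type] += 1
    out = []
    for gene in sorted(per_gene):
        n, s = per_gene[gene]["N"], per_gene[gene]["S"]
        if s > 0:
            dnds = n / s
            if dnds < low:
                sel = "purifying"
            elif dnds > high:
                sel = "positive"
            else:
                sel = "neutral-range"
        else:
            dnds, sel = None, "undefined"
        out.append(GeneSelection(gene=gene, protein=per_gene[gene]["protein"],
                                 n_count=n, s_count=s, dnds=dnds,
                                 selection_class=sel))
    return out


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal place."""
    if denom == 0:
        return float("nan")
    return float(Decimal(100 * numer / denom).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_annotation(consequences) -> dict:
    """Deterministic tallies over a set of annotated SNVs.

    Returns counts of coding/non-coding SNVs (with the coding percentage
    to one decimal), the N/S split, the collapsed substitution-class
    spectrum and the distinct affected proteins.
    """
    consequences = list(consequences)
    coding = [c for c in consequences if c.mutation_type in ("N", "S")]
    class_counts = Counter(c.collapsed_class for c in consequences)
    proteins = sorted({c.protein for c in coding if c.protein})
    return {
        "n_total": len(consequences),
        "n_coding": len(coding),
        "n_noncoding": len(consequences) - len(coding),
        "pct_coding": _pct(len(coding), len(consequences)),
        "n_synonymous": sum(c.mutation_type == "S" for c in coding),
        "n_nonsynonymous": sum(c.mutation_type == "N" for c in coding),
        "class_counts": dict(sorted(class_counts.items())),
        "n_classes": len(class_counts),
        "proteins": proteins,
        "n_proteins": len(proteins),
    }


def consequences_from_table(df, genome_id: str = "F_prausnitzii_ATCC27768",
                            table: int = DEFAULT_CODON_TABLE
                            ) -> list[CodonConsequence]:
    """Build consequences from an annotation table (e.g. the packaged fixture).

    Expects columns position, ref_base, alt_base, ref_codon, alt_codon and
    protein. For coding rows the N/S type is recomputed by translating the
    REF and ALT codons rather than trusted from the table, so tallies over
    the result genuinely exercise the classifier.
    """
    out = []
    for r in df.itertuples():
        key = SnvKey(genome_id, int(r.position), r.ref_base, r.alt_base)
        cclass = collapse_class(key)
        coding = isinstance(r.ref_codon, str)
        if not coding:
            out.append(CodonConsequence(
                key=key, gene=None, strand=None, codon_index=None,
                ref_codon=None, alt_codon=None, ref_aa=None, alt_aa=None,
                mutation_type="noncoding", protein=None,
                collapsed_class=cclass))
            continue
        mtype = classify_ns(r.ref_codon, r.alt_codon, table=table)
        ref_aa = _translate(r.ref_codon, table)
        alt_aa = _translate(r.alt_codon, table)
        order = getattr(r, "gene_order", None)
        gene = f"gene_{int(order)}" if order is not None and order == order \
            else f"pos_{r.position}"
        out.append(CodonConsequence(
            key=key, gene=gene, strand=None, codon_index=None,
            ref_codon=r.ref_codon, alt_codon=r.alt_codon,
            ref_aa=ref_aa, alt_aa=alt_aa, mutation_type=mtype,
            protein=r.protein, collapsed_class=cclass,
            nonsense="*" in (ref_aa, alt_aa)))
    return out


def all_codon_tables() -> list[int]:
    """Available NCBI genetic-code table ids (for configuration validation)."""
    return sorted(CodonTable.unambiguous_dna_by_id)
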