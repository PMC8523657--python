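"""Codon mapping, N/S classification (vs brute-force oracle), class collapse,
per-gene dN/dS and the annotation summary on the packaged worked example."""

import itertools

import pytest
from Bio.Data import CodonTable
from hypothesis import given
from hypothesis import strategies as st

from adaptsnv.adaptive import SnvKey
from adaptsnv.annotate import (AnnotationError, classify_ns, collapse_class,
                               consequences_from_table, gene_dnds,
                               map_to_codon, summarize_annotation)
from adaptsnv.simulate import Gene

BASES = "ACGT"


def oracle_classify(ref_codon, alt_codon, table_id=11):
    """Independent route: translate via the raw NCBI codon table mapping."""
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    aa = lambda c: tab.forward_table.get(c, "*")
    return "S" if aa(ref_codon) == aa(alt_codon) else "N"


class TestClassifyNS:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("GAG", "AAG", "N"),  # E -> K
        ("GGT", "GGC", "S"),  # G -> G
        ("GAT", "GAC", "S"),  # D -> D
        ("TCA", "ACA", "N"),  # S -> T
    ])
    def test_worked_examples(self, ref, alt, expected):
        assert classify_ns(ref, alt) == expected

    def test_matches_oracle_on_all_576_single_substitution_pairs(self):
        n_pairs = 0
        for codon in itertools.product(BASES, repeat=3):
            codon = "".join(codon)
            for i, alt_base in itertools.product(range(3), BASES):
                if alt_base == codon[i]:
                    continue
                alt = codon[:i] + alt_base + codon[i + 1:]
                assert classify_ns(codon, alt) == oracle_classify(codon, alt)
                n_pairs += 1
        assert n_pairs == 576

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            classify_ns("AAA", "AAA")
        with pytest.raises(ValueError):
            classify_ns("AAA", "CCA")
        with pytest.raises(ValueError):
            classify_ns("ANA", "AAA")


class TestCollapseClass:
    @pytest.mark.parametrize("frm,to,expected", [
        ("C", "T", "G>A"), ("A", "G", "A>G"), ("T", "G", "A>C"),
        ("G", "T", "G>T"), ("T", "C", "A>G"), ("C", "A", "G>T"),
    ])
    def test_purine_reference_rule(self, frm, to, expected):
        assert collapse_class(frm, to) == expected

    @given(st.sampled_from(BASES), st.sampled_from(BASES))
    def test_projection_and_strand_symmetry(self, frm, to):
        if frm == to:
            return
        collapsed = collapse_class(frm, to)
        # idempotent projection
        assert collapse_class(*collapsed.split(">")) == collapsed
        # complementing both alleles leaves the class unchanged
        comp = str.maketrans(BASES, "TGCA")
        assert collapse_class(frm.translate(comp),
                              to.translate(comp)) == collapsed
        assert collapsed[0] in "AG"

    def test_only_six_classes_possible(self):
        classes = {collapse_class(f, t) for f in BASES for t in BASES
                   if f != t}
        assert classes == {"A>G", "A>C", "A>T", "G>A", "G>T", "G>C"}


class TestMapToCodon:
    GENOME = "A" * 9 + "ATGGAAGATTGA" + "C" * 9  # +strand CDS at 10..21

    def test_plus_strand_coding(self):
        gene = Gene("g", 10, 21, "+", "demo protein")
        # position 13 is codon 2 base 1: GAA (E); A->G gives... G A A -> GGA
        c = map_to_codon(SnvKey("g1", 13, "G", "A"), [gene], self.GENOME)
        assert (c.codon_index, c.ref_codon, c.alt_codon) == (2, "GAA", "AAA")
        assert (c.ref_aa, c.alt_aa, c.mutation_type) == ("E", "K", "N")
        assert c.protein == "demo protein"

    def test_minus_strand_equals_reverse_complement_plus(self):
        """Annotating a minus-strand gene matches annotating the reverse
        complement genome on the plus strand."""
        comp = str.maketrans(BASES, "TGCA")
        genome = self.GENOME
        rc = genome[::-1].translate(comp)
        L = len(genome)
        gene_minus = Gene("g", 10, 21, "-", "p")
        gene_plus = Gene("g", L - 21 + 1, L - 10 + 1, "+", "p")
        for pos, frm, to in [(13, "G", "A"), (20, "G", "C"), (10, "A", "C")]:
            c_minus = map_to_codon(SnvKey("g1", pos, frm, to),
                                   [gene_minus], genome)
            c_plus = map_to_codon(
                SnvKey("g1", L - pos + 1, frm.translate(comp),
                       to.translate(comp)), [gene_plus], rc)
            assert (c_minus.ref_codon, c_minus.alt_codon,
                    c_minus.mutation_type) == \
                (c_plus.ref_codon, c_plus.alt_codon, c_plus.mutation_type)

    def test_intergenic_position_is_noncoding(self):
        gene = Gene("g", 10, 21, "+", "p")
        c = map_to_codon(SnvKey("g1", 3, "A", "G"), [gene], self.GENOME)
        assert c.mutation_type == "noncoding"
        assert c.protein is None

    def test_no_genes_everything_noncoding(self):
        c = map_to_codon(SnvKey("g1", 5, "A", "G"), [], self.GENOME)
        assert c.mutation_type == "noncoding"

    def test_out_of_frame_gene_rejected(self):
        gene = Gene("g", 10, 20, "+", "p")  # length 11
        with pytest.raises(AnnotationError):
            map_to_codon(SnvKey("g1", 12, "G", "A"), [gene], self.GENOME)

    def test_nonsense_change_flagged_and_typed_n(self):
        gene = Gene("g", 10, 21, "+", "p")
        # codon 4 TGA(stop) -> CGA (R): nonsense, N
        c = map_to_codon(SnvKey("g1", 19, "T", "C"), [gene], self.GENOME)
        assert c.nonsense and c.mutation_type == "N"

    def test_synthetic_genome_self_consistency(self, reference):
        """On the simulator's genome, substituting the reference base into
        its own codon reproduces the genomic codon."""
        for gene in reference.genes[:10]:
            pos = gene.start + 4
            ref_base = reference.sequence[pos - 1]
            alt = next(b for b in BASES if b != ref_base)
            c = map_to_codon(SnvKey("g", pos, ref_base, alt),
                             reference.genes, reference.sequence)
            assert c.mutation_type in ("N", "S")
            # ref codon must embed the genomic context
            cds = reference.sequence[gene.start - 1:gene.end]
            if gene.strand == "-":
                cds = cds[::-1].translate(str.maketrans(BASES, "TGCA"))
            assert c.ref_codon == cds[3 * (c.codon_index - 1):
                                      3 * c.codon_index]


class TestGeneDnds:
    @staticmethod
    def _cons(gene, mtype, pos=0):
        from types import SimpleNamespace

        return SimpleNamespace(gene=gene, protein=gene, mutation_type=mtype,
                               key=pos)

    def test_threshold_classes(self):
        rows = ([self._cons("a", "N", 0)] * 2 + [self._cons("a", "S", 0)]
                + [self._cons("b", "S", 0)] * 3
                + [self._cons("c", "N", 0)] * 4)
        sel = {s.gene: s for s in gene_dnds(rows)}
        assert sel["a"].dnds == pytest.approx(2.0)
        assert sel["a"].selection_class == "positive"
        assert sel["b"].dnds == 0.0
        assert sel["b"].selection_class == "purifying"
        assert sel["c"].dnds is None
        assert sel["c"].selection_class == "undefined"

    def test_order_invariance(self):
        rows = [self._cons(g, t, 0) for g, t in
                [("a", "N"), ("b", "S"), ("a", "S"), ("b", "N"), ("a", "N")]]
        fwd = gene_dnds(rows)
        rev = gene_dnds(rows[::-1])
        assert fwd == rev


class TestFixtureSummary:
    def test_six_synonymous_coding_snvs(self, table3):
        s = summarize_annotation(consequences_from_table(table3))
        assert s["n_synonymous"] == 6

    def test_nine_distinct_proteins(self, table3):
        s = summarize_annotation(consequences_from_table(table3))
        assert s["n_proteins"] == 9

    def test_four_collapsed_substitution_classes(self, table3):
        s = summarize_annotation(consequences_from_table(table3))
        assert s["n_classes"] == 4
        assert set(s["class_counts"]) == {"A>G", "A>C", "G>A", "G>T"}

    def test_recomputed_types_match_printed_types(self, table3):
        cons = {c.key.position: c for c in consequences_from_table(table3)}
        for r in table3.itertuples():
            assert cons[r.position].mutation_type == r.mutation_type
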