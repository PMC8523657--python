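"""Retained-vs-transient partition of endpoint SNVs at a follow-up phase.

Phase I is the set of SNVs detected at the end of the intervention; phase
II is the set detected months later against the same baseline. Phase-I
SNVs still present at phase II are *retained* (heritable); those no longer
detectable are *transient*. SNVs appearing only at phase II are novel and
are reported but not classified. Affected proteins are compared across the
two classes as a three-part Venn, and proteins are called *entirely
inherited* (all of their phase-I SNVs retained, with a minimum count) or
*transient* (enough transient SNVs and no retained one).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

DEFAULT_MIN_SNVS = 2


@dataclass
class HeritabilityResult:
    phase1: set
    phase2: set
    retained: set
    transient: set
    novel_at_phase2: set
    retained_fraction: float | None  # None when phase1 is empty


@dataclass
class ProteinVenn:
    unique_heritable: set[str]
    unique_transient: set[str]
    shared: set[str]

    @property
    def union_size(self) -> int:
        return (len(self.unique_heritable) + len(self.unique_transient)
                + len(self.shared))


def partition_heritability(phase1: set, phase2: set) -> HeritabilityResult:
    """Partition phase-I SNVs into retained (also in phase II) and transient.

    ``|retained| + |transient| == |phase1|`` always;
    ``retained_fraction = |retained| / |phase1|`` (undefined for empty
    phase I).
    """
    phase1, phase2 = set(phase1), set(phase2)
    retained = phase1 & phase2
    transient = phase1 - phase2
    frac = len(retained) / len(phase1) if phase1 else None
    return HeritabilityResult(phase1=phase1, phase2=phase2,
                              retained=retained, transient=transient,
                              novel_at_phase2=phase2 - phase1,
                              retained_fraction=frac)


def _protein_of(entry) -> str | None:
    protein = getattr(entry, "protein", entry if isinstance(entry, str) else None)
    mtype = getattr(entry, "mutation_type", None)
    if mtype == "noncoding":
        return None
    return protein


def protein_venn(retained_annot, transient_annot) -> ProteinVenn:
    """Three-part Venn of proteins hit by retained vs transient SNVs.

    Inputs are annotated consequences (or bare protein names); non-coding
    entries are excluded. The three parts are pairwise disjoint and sum to
    the size of the union.
    """
    h = {p for p in map(_protein_of, retained_annot) if p}
    t = {p for p in map(_protein_of, transient_annot) if p}
    return ProteinVenn(unique_heritable=h - t, unique_transient=t - h,
                       shared=h & t)


def classify_proteins(retained_annot, transient_annot,
                      min_snvs: int = DEFAULT_MIN_SNVS
                      ) -> tuple[set[str], set[str]]:
    """Call proteins entirely inherited or transient.

    *Entirely inherited*: every phase-I SNV of the protein was retained,
    and at least ``min_snvs`` of them were. *Transient*: at least
    ``min_snvs`` transient SNVs and no retained one.
    """
    if min_snvs < 1:
        raise ValueError("min_snvs must be >= 1")
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])  # [ret, tra]
    for entry in retained_annot:
        p = _protein_of(entry)
        if p:
            counts[p][0] += 1
    for entry in transient_annot:
        p = _protein_of(entry)
        if p:
            counts[p][1] += 1
    entirely = {p for p, (r, t) in counts.items()
                if t == 0 and r >= min_snvs}
    transient_proteins = {p for p, (r, t) in counts.items()
                          if r == 0 and t >= min_snvs}
    return entirely, transient_proteins
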