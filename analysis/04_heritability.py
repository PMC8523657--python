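#!/usr/bin/env python
"""Step 4: partition intervention-phase adaptive SNVs into retained vs
transient at follow-up, with a protein-level Venn.

Reads results/adaptive_snvs.tsv (T1) and results/adaptive_snvs_T2.tsv, plus
the reference for protein assignment; writes results/heritability.json.
"""

import json

import pandas as pd

from _common import RESULTS, SIM_DIR
from adaptsnv import io as aio
from adaptsnv.adaptive import SnvKey
from adaptsnv.annotate import map_to_codon
from adaptsnv.heritability import (classify_proteins, partition_heritability,
                                   protein_venn)


def _keys(path):
    df = pd.read_csv(path, sep="\t")
    df = df[df.universal]
    return {SnvKey(r.genome_id, int(r.position), r.from_allele, r.to_allele)
            for r in df.itertuples()}


def main() -> None:
    phase1 = _keys(RESULTS / "adaptive_snvs.tsv")
    phase2 = _keys(RESULTS / "adaptive_snvs_T2.tsv")
    part = partition_heritability(phase1, phase2)

    _, genome = aio.read_reference_fasta(str(SIM_DIR / "reference.fasta"))
    genes = aio.read_gene_models(str(SIM_DIR / "genes.gff3"))
    annot = lambda keys: [map_to_codon(k, genes, genome) for k in sorted(keys)]
    retained, transient = annot(part.retained), annot(part.transient)
    venn = protein_venn(retained, transient)
    entirely, trans_prot = classify_proteins(retained, transient)

    payload = {
        "n_phase1": len(part.phase1), "n_phase2": len(part.phase2),
        "n_retained": len(part.retained), "n_transient": len(part.transient),
        "retained_fraction": part.retained_fraction,
        "venn": {"unique_heritable": len(venn.unique_heritable),
                 "shared": len(venn.shared),
                 "unique_transient": len(venn.unique_transient),
                 "union": venn.union_size},
        "entirely_inherited_proteins": sorted(entirely),
        "transient_proteins": sorted(trans_prot),
    }
    (RESULTS / "heritability.json").write_text(json.dumps(payload, indent=2)
                                               + "\n")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
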