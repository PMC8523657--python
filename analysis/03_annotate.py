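#!/usr/bin/env python
"""Step 3: annotate the universal adaptive SNVs to codons, amino-acid changes
and per-gene dN/dS.

Reads results/adaptive_snvs.tsv + results/sim reference; writes
results/annotation.tsv, results/gene_selection.tsv and
results/annotation_summary.json.
"""

import dataclasses
import json

import pandas as pd

from _common import RESULTS, SIM_DIR
from adaptsnv import io as aio
from adaptsnv.adaptive import SnvKey
from adaptsnv.annotate import gene_dnds, map_to_codon, summarize_annotation


def main() -> None:
    df = pd.read_csv(RESULTS / "adaptive_snvs.tsv", sep="\t")
    df = df[df.universal]
    _, genome = aio.read_reference_fasta(str(SIM_DIR / "reference.fasta"))
    genes = aio.read_gene_models(str(SIM_DIR / "genes.gff3"))

    cons, rows = [], []
    for r in df.itertuples():
        key = SnvKey(r.genome_id, int(r.position), r.from_allele, r.to_allele)
        c = map_to_codon(key, genes, genome)
        cons.append(c)
        rows.append({**dataclasses.asdict(c), "position": key.position})

    pd.DataFrame(rows).to_csv(RESULTS / "annotation.tsv", sep="\t",
                              index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in gene_dnds(cons)]) \
        .to_csv(RESULTS / "gene_selection.tsv", sep="\t", index=False)

    summary = summarize_annotation(cons)
    (RESULTS / "annotation_summary.json").write_text(
        json.dumps(summary, indent=2, default=list) + "\n")
    print(json.dumps(summary, indent=2, default=list))


if __name__ == "__main__":
    main()
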