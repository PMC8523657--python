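#!/usr/bin/env python
"""Step 5: community-level statistics on the simulated cohort.

Per-sample alpha diversity of the species abundance table, Bray-Curtis
PERMANOVA of endpoint samples across study arms, and a rank-sum test of
depth-normalized SNV burden (nSNV) between arms. Writes results/stats.tsv.
"""

import argparse

import pandas as pd

from _common import DEFAULT_SEED, RESULTS, SIM_DIR
from adaptsnv import io as aio
from adaptsnv.stats import (distance_matrix, permanova, shannon, simpson,
                            wilcoxon_rank_sum)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--permutations", type=int, default=999)
    args = ap.parse_args()

    meta = aio.read_metadata(str(SIM_DIR / "metadata.tsv"))
    # taxon rows x sample columns on disk; transpose to samples x taxa
    abundance = pd.read_csv(SIM_DIR / "abundance.tsv", sep="\t",
                            index_col=0).T
    nsnv = pd.read_csv(RESULTS / "nsnv.tsv", sep="\t").set_index("sample_id")

    rows = []
    for sid in abundance.index:
        rows.append({"test": "shannon", "sample_id": sid,
                     "statistic": shannon(abundance.loc[sid]),
                     "p_value": None})
        rows.append({"test": "simpson", "sample_id": sid,
                     "statistic": simpson(abundance.loc[sid]),
                     "p_value": None})

    endpoint = meta[meta.timepoint == "T1"].set_index("sample_id")
    prof = abundance.loc[endpoint.index]
    dm = distance_matrix(prof)
    pv = permanova(dm, endpoint.arm.tolist(),
                   n_permutations=args.permutations, seed=args.seed)
    rows.append({"test": "permanova_arm_braycurtis", "sample_id": None,
                 "statistic": pv.statistic, "p_value": pv.p_value})

    arm_nsnv = nsnv.join(endpoint[["arm"]], how="inner")
    ws = wilcoxon_rank_sum(arm_nsnv[arm_nsnv.arm == "probiotic"].nsnv,
                           arm_nsnv[arm_nsnv.arm == "control"].nsnv)
    rows.append({"test": "wilcoxon_nsnv_probiotic_vs_control",
                 "sample_id": None, "statistic": ws.statistic,
                 "p_value": ws.p_value})

    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "stats.tsv", sep="\t", index=False)
    print(out[out.p_value.notna()].to_string(index=False))


if __name__ == "__main__":
    main()
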