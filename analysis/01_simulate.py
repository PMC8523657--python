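#!/usr/bin/env python
"""Step 1: simulate a six-study longitudinal cohort with a follow-up phase.

Writes reference FASTA/GFF3, per-sample VCFs, metadata, abundance and the
planted truth set under results/sim/.
"""

import argparse
import json

from _common import DEFAULT_SEED, SIM_DIR
from adaptsnv.simulate import (SimConfig, generate_reference, simulate_cohort,
                               write_cohort)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed, n_studies=6, hosts_per_study=10,
                    control_fraction=0.5, n_planted_adaptive=5,
                    planted_prevalence=0.6, planted_study_support=3,
                    n_background_per_host=200, n_control_shared=2,
                    followup=True, retained_fraction=0.6)
    sim = simulate_cohort(cfg, generate_reference(cfg))
    paths = write_cohort(sim, str(SIM_DIR))
    print(json.dumps(paths, indent=2))


if __name__ == "__main__":
    main()
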