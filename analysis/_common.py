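"""Shared paths and loaders for the numbered analysis drivers."""

from __future__ import annotations

import os
from pathlib import Path

from adaptsnv import io as aio

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

DEFAULT_SEED = 17


def load_cohort(quality_min: float = 60.0, depth_min: int = 100):
    """Metadata DataFrame + filtered SnvCall tables from results/sim."""
    meta = aio.read_metadata(str(SIM_DIR / "metadata.tsv"))
    tables = {}
    for row in meta.itertuples():
        path = os.path.join(SIM_DIR, "snv", f"{row.sample_id}.vcf")
        tables[row.sample_id] = aio.read_snv_table(
            path, quality_min, depth_min, sample_id=row.sample_id)
    return meta, tables
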