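"""End-to-end orchestration: simulate -> filter -> detect -> annotate -> heritability -> stats.

``run_all`` executes the stages in order against a run directory, writing
each stage's tables under fixed names plus a JSON run report echoing the
configuration, the seeds used and per-stage record counts. A failing stage
leaves a ``<stage>.partial`` marker next to the outputs already written
and raises :class:`StageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import pandas as pd

import adaptsnv
from adaptsnv import io as aio
from adaptsnv import stats as astats
from adaptsnv.adaptive import MetaConfig, run_meta_analysis
from adaptsnv.annotate import gene_dnds, map_to_codon, summarize_annotation
from adaptsnv.heritability import (classify_proteins, partition_heritability,
                                   protein_venn)
from adaptsnv.simulate import SimConfig, generate_reference, simulate_cohort, \
    write_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialized verbatim into the report)."""

    seed: int = 0
    simulate: bool = False
    # input paths (ignored when simulate=True; filled from the simulation)
    snv_dir: str | None = None
    metadata: str | None = None
    abundance: str | None = None
    fasta: str | None = None
    gff: str | None = None
    # thresholds
    quality_min: float = aio.DEFAULT_QUALITY_MIN
    depth_min: int = aio.DEFAULT_DEPTH_MIN
    abundance_min: float = aio.DEFAULT_ABUNDANCE_MIN
    prevalence: float = 0.5
    study_min: int = 3
    dnds_low: float = 0.25
    dnds_high: float = 1.0
    min_snvs_protein: int = 2
    null_model: str = "control-arm"
    position_only: bool = False
    permutations: int = 999
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.abundance_min <= 1):
            raise ValueError("abundance_min must be in [0, 1]")
        if not (0 < self.prevalence <= 1):
            raise ValueError("prevalence must be in (0, 1]")
        if self.dnds_low < 0 or self.dnds_high < self.dnds_low:
            raise ValueError("require 0 <= dnds_low <= dnds_high")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def run_all(config: RunConfig, outdir: str) -> dict:
    """Execute the full pipeline; returns the run report (also written as JSON)."""
    os.makedirs(outdir, exist_ok=True)
    config = dataclasses.replace(config)  # never mutate the caller's config
    report: dict = {
        "versions": {"adaptsnv": adaptsnv.__version__,
                     "python": platform.python_version()},
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "setup"

    def _marker(st: str) -> None:
        with open(os.path.join(outdir, f"{st}.partial"), "w") as fh:
            fh.write("stage did not complete\n")

    try:
        truth = None
        if config.simulate:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            reference = generate_reference(sim_cfg)
            sim = simulate_cohort(sim_cfg, reference)
            paths = write_cohort(sim, os.path.join(outdir, "sim"))
            config.snv_dir = paths["snv_dir"]
            config.metadata = paths["metadata"]
            config.abundance = paths["abundance"]
            config.fasta = paths["fasta"]
            config.gff = paths["gff"]
            truth = sim.truth
            report["stages"]["simulate"] = {
                "n_samples": len(sim.samples),
                "n_planted_adaptive": len(sim.truth.planted_adaptive),
                "n_control_shared": len(sim.truth.control_shared),
            }

        stage = "load"
        for name in ("snv_dir", "metadata", "abundance"):
            path = getattr(config, name)
            if path is None or not os.path.exists(path):
                raise FileNotFoundError(f"required input '{name}' missing: "
                                        f"{path}")
        meta = aio.read_metadata(config.metadata)
        abundance = aio.read_abundance(config.abundance)
        species = set()
        for study, cols in meta.groupby("study")["sample_id"]:
            present = [c for c in cols if c in abundance.columns]
            if present:
                species |= set(aio.select_species(abundance[present],
                                                  config.abundance_min))
        snv_tables = {}
        n_calls = 0
        for row in meta.itertuples():
            path = os.path.join(config.snv_dir, f"{row.sample_id}.vcf")
            calls = aio.read_snv_table(path, config.quality_min,
                                       config.depth_min,
                                       sample_id=row.sample_id)
            snv_tables[row.sample_id] = calls
            n_calls += len(calls)
        report["stages"]["load"] = {"n_samples": len(meta),
                                    "n_selected_species": len(species),
                                    "n_filtered_calls": n_calls}

        stage = "detect"
        mconf = MetaConfig(prevalence_threshold=config.prevalence,
                           study_min=config.study_min,
                           null_model=config.null_model,
                           position_only=config.position_only)
        result = run_meta_analysis(meta, snv_tables, mconf)
        result.table.assign(per_study_prevalence=result.table
                            .per_study_prevalence.map(json.dumps)) \
            .to_csv(os.path.join(outdir, "adaptive_snvs.tsv"), sep="\t",
                    index=False)
        result.normalization.to_csv(os.path.join(outdir, "nsnv.tsv"),
                                    sep="\t", index=False)
        report["stages"]["detect"] = {
            "n_candidates": int(len(result.table)),
            "n_null_excluded": len(result.null_excluded),
            "n_universal": len(result.universal),
            "n_unmatched_hosts_dropped": result.n_unmatched_hosts,
        }
        if truth is not None:
            planted = truth.adaptive_keys(config.sim.genome_id)
            recovered = {(k.genome_id, k.position, k.from_allele, k.to_allele)
                         for k in result.universal}
            tp = len(planted & recovered)
            report["stages"]["detect"]["recovery"] = {
                "n_planted": len(planted),
                "n_recovered": len(recovered),
                "sensitivity": tp / len(planted) if planted else None,
                "precision": tp / len(recovered) if recovered else None,
            }

        stage = "annotate"
        annotation_rows = []
        consequences = []
        genes, genome = [], ""
        if config.fasta and config.gff and os.path.exists(config.fasta):
            _, genome = aio.read_reference_fasta(config.fasta)
            genes = aio.read_gene_models(config.gff)
            for key in sorted(result.universal):
                c = map_to_codon(key, genes, genome)
                consequences.append(c)
                annotation_rows.append({
                    "genome_id": key.genome_id, "position": key.position,
                    "from_allele": key.from_allele, "to_allele": key.to_allele,
                    "gene": c.gene, "strand": c.strand,
                    "codon_index": c.codon_index, "ref_codon": c.ref_codon,
                    "alt_codon": c.alt_codon, "ref_aa": c.ref_aa,
                    "alt_aa": c.alt_aa, "mutation_type": c.mutation_type,
                    "protein": c.protein,
                    "collapsed_class": c.collapsed_class,
                    "nonsense": c.nonsense})
        pd.DataFrame(annotation_rows).to_csv(
            os.path.join(outdir, "annotation.tsv"), sep="\t", index=False)
        selections = gene_dnds(consequences, config.dnds_low,
                               config.dnds_high)
        pd.DataFrame([dataclasses.asdict(s) for s in selections]).to_csv(
            os.path.join(outdir, "gene_selection.tsv"), sep="\t", index=False)
        report["stages"]["annotate"] = {
            "summary": summarize_annotation(consequences),
            "n_genes_with_dnds": sum(s.dnds is not None for s in selections),
        }

        if "T2" in set(meta.timepoint):
            stage = "heritability"
            phase2 = run_meta_analysis(meta, snv_tables, mconf, endpoint="T2")
            part = partition_heritability(result.universal, phase2.universal)
            by_key = {c.key: c for c in consequences}

            def annot(keys):
                if not genome:  # no reference: protein-level calls skipped
                    return []
                return [by_key.get(k) or map_to_codon(k, genes, genome)
                        for k in sorted(keys)]

            ret_annot, tra_annot = annot(part.retained), annot(part.transient)
            venn = protein_venn(ret_annot, tra_annot)
            entirely, transient_prot = classify_proteins(
                ret_annot, tra_annot, config.min_snvs_protein)
            herit_rows = [{"genome_id": k.genome_id, "position": k.position,
                           "from_allele": k.from_allele,
                           "to_allele": k.to_allele,
                           "status": ("retained" if k in part.retained
                                      else "transient")}
                          for k in sorted(part.phase1)]
            pd.DataFrame(herit_rows).to_csv(
                os.path.join(outdir, "heritability.tsv"), sep="\t",
                index=False)
            venn_payload = {
                "n_phase1": len(part.phase1), "n_phase2": len(part.phase2),
                "n_retained": len(part.retained),
                "n_transient": len(part.transient),
                "retained_fraction": part.retained_fraction,
                "protein_venn": {
                    "unique_heritable": sorted(venn.unique_heritable),
                    "unique_transient": sorted(venn.unique_transient),
                    "shared": sorted(venn.shared)},
                "entirely_inherited_proteins": sorted(entirely),
                "transient_proteins": sorted(transient_prot)}
            with open(os.path.join(outdir, "heritability_venn.json"),
                      "w") as fh:
                json.dump(venn_payload, fh, indent=2, sort_keys=True)
            report["stages"]["heritability"] = {
                k: venn_payload[k]
                for k in ("n_phase1", "n_phase2", "n_retained", "n_transient",
                          "retained_fraction")}

        stage = "stats"
        stat_rows = []
        norm = result.normalization.merge(
            meta[["sample_id", "study", "host", "arm", "timepoint"]],
            on="sample_id")
        cor = astats.correlate(norm.raw_snv_count, norm.sequencing_depth)
        stat_rows.append({"test": "pearson raw SNV count vs depth",
                          "statistic": cor.statistic, "p_value": cor.p_value,
                          "n": len(norm), "seed": None})
        t0 = norm.loc[norm.timepoint == "T0", "nsnv"]
        t1 = norm.loc[norm.timepoint == "T1", "nsnv"]
        if len(t0) and len(t1):
            w = astats.wilcoxon_rank_sum(t0, t1)
            stat_rows.append({"test": "wilcoxon nsnv T0 vs T1",
                              "statistic": w.statistic, "p_value": w.p_value,
                              "n": len(t0) + len(t1), "seed": None})
        t1_meta = meta[meta.timepoint == "T1"]
        profiles = abundance[t1_meta.sample_id].T
        if t1_meta.arm.nunique() >= 2 and \
                t1_meta.arm.value_counts().min() >= 2:
            dm = astats.distance_matrix(profiles)
            perm_seed = _stage_seed(config.seed, 5)
            pv = astats.permanova(dm, t1_meta.arm.tolist(),
                                  n_permutations=config.permutations,
                                  seed=perm_seed)
            stat_rows.append({"test": "permanova abundance ~ arm (T1)",
                              "statistic": pv.statistic,
                              "p_value": pv.p_value, "n": len(profiles),
                              "seed": perm_seed})
        pd.DataFrame(stat_rows).to_csv(os.path.join(outdir, "stats.tsv"),
                                       sep="\t", index=False)
        report["stages"]["stats"] = {"n_tests": len(stat_rows)}

        stage = "report"
        report["seed"] = config.seed
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
        return report
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        _marker(stage)
        raise StageError(stage, exc) from exc
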