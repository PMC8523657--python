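"""Detection of probiotic-induced adaptive SNVs from paired longitudinal calls.

The definition implemented here has four stages:

1. **Within-host differential detection** — for every host, compare the
   effective allele at each genomic position between baseline (T0) and
   endpoint (T1). The effective allele is the called ALT when a call
   exists, and the reference base otherwise, so a change is detected even
   when one of the two timepoints matches the reference (including
   reversions). Each change is keyed by (genome, position, from->to allele).
2. **Prevalence filter** — within a study, keep changes observed in at
   least a threshold fraction of hosts (30% and 50% are the conventional
   settings; 50% is the default).
3. **Null-model exclusion** — discard changes that also arise in
   control-arm hosts over a matched period with no probiotic exposure.
4. **Universality** — keep changes detected in at least ``study_min``
   independent studies (default 3, i.e. half of a six-study panel).

Per-sample SNV burdens are normalized by sequencing depth
(``nsnv = raw count / depth``) to make them comparable across studies.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PREVALENCE = 0.5
#: laxer preset from the "at least 30/50% of hosts" convention
PREVALENCE_PRESETS = {"strict": 0.5, "lenient": 0.3}
DEFAULT_STUDY_MIN = 3


@dataclass(frozen=True, order=True)
class SnvKey:
    """Identity of a within-host single-nucleotide change."""

    genome_id: str
    position: int  # 1-based
    from_allele: str
    to_allele: str

    def __post_init__(self) -> None:
        if self.from_allele == self.to_allele:
            raise ValueError("from_allele must differ from to_allele")


@dataclass
class NormalizationResult:
    sample_id: str
    raw_snv_count: int
    sequencing_depth: float
    nsnv: float


@dataclass
class MetaConfig:
    """Thresholds for the adaptive-SNV meta-analysis."""

    prevalence_threshold: float = DEFAULT_PREVALENCE
    study_min: int = DEFAULT_STUDY_MIN
    null_model: str = "control-arm"  # 'control-arm' | 'off'
    position_only: bool = False  # lax cross-host matching by position alone

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_threshold <= 1.0):
            raise ValueError("prevalence_threshold must be in (0, 1]")
        if self.study_min < 1:
            raise ValueError("study_min must be >= 1")
        if self.null_model not in ("control-arm", "off"):
            raise ValueError("null_model must be 'control-arm' or 'off'")


@dataclass
class AdaptiveResult:
    """Output of :func:`run_meta_analysis`."""

    table: pd.DataFrame  # one row per candidate SnvKey
    universal: set[SnvKey]
    normalization: pd.DataFrame  # per-sample nsnv
    per_study_retained: dict[str, set[SnvKey]]
    null_excluded: set[SnvKey]
    n_unmatched_hosts: int
    config: MetaConfig = field(default_factory=MetaConfig)


def normalize_snv_count(raw_count: int, depth: float) -> float:
    """Depth-normalized SNV burden: ``raw_count / depth``."""
    if depth <= 0:
        raise ValueError("sequencing depth must be > 0")
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    return raw_count / depth


def _allele_map(calls) -> dict[int, tuple[str, str]]:
    """position -> (ref, alt); error on conflicting duplicates."""
    out: dict[int, tuple[str, str]] = {}
    for c in calls:
        prev = out.get(c.position)
        cur = (c.ref_allele, c.alt_allele)
        if prev is not None and prev != cur:
            raise ValueError(
                f"conflicting duplicate calls at position {c.position} "
                f"in sample {getattr(c, 'sample_id', '?')}")
        out[c.position] = cur
    return out


def host_differential_snvs(calls_t0, calls_t1) -> set[SnvKey]:
    """Single-nucleotide changes between a host's baseline and endpoint.

    The host's effective allele at a position is the called ALT when a
    call exists at that timepoint and the reference base otherwise, so a
    change is emitted whether or not either timepoint matches the
    reference (a reversion ALT->REF counts). Positions with no call at
    either timepoint are never emitted; detection is therefore blind to
    changes the upstream caller did not report at either end.
    """
    t0 = _allele_map(calls_t0)
    t1 = _allele_map(calls_t1)
    genomes = {c.genome_id for c in calls_t0} | {c.genome_id for c in calls_t1}
    if len(genomes) > 1:
        raise ValueError(f"calls span multiple genomes: {sorted(genomes)}")
    genome_id = genomes.pop() if genomes else ""

    keys: set[SnvKey] = set()
    for pos in t0.keys() | t1.keys():
        ref = (t0.get(pos) or t1.get(pos))[0]
        a0 = t0[pos][1] if pos in t0 else ref
        a1 = t1[pos][1] if pos in t1 else ref
        if a0 != a1:
            keys.add(SnvKey(genome_id, pos, a0, a1))
    return keys


def prevalence_filter(host_sets: dict[str, set[SnvKey]],
                      threshold: float = DEFAULT_PREVALENCE
                      ) -> tuple[dict[SnvKey, float], set[SnvKey]]:
    """Per-key prevalence across hosts plus the keys meeting ``threshold``.

    Prevalence is the fraction of hosts whose differential set contains
    the key; retention is inclusive (prevalence >= threshold).
    """
    if not host_sets:
        raise ValueError("host_sets must contain at least one host")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    n_hosts = len(host_sets)
    counts = Counter(k for s in host_sets.values() for k in s)
    prevalence = {k: c / n_hosts for k, c in counts.items()}
    retained = {k for k, p in prevalence.items() if p >= threshold}
    return prevalence, retained


def null_model_exclude(candidates: set[SnvKey],
                       control_sets: dict[str, set[SnvKey]]
                       ) -> tuple[set[SnvKey], set[SnvKey]]:
    """Drop candidates that also occur in any control-arm host.

    Returns ``(retained, excluded)``. An empty control union retains all
    candidates but logs a warning that the null model is vacuous.
    """
    control_union: set[SnvKey] = set()
    for s in control_sets.values():
        control_union |= s
    if not control_union:
        logger.warning("null model is vacuous: no control-arm changes "
                       "observed; nothing excluded")
    excluded = candidates & control_union
    return candidates - excluded, excluded


def universality(per_study_retained: dict[str, set[SnvKey]],
                 study_min: int = DEFAULT_STUDY_MIN) -> set[SnvKey]:
    """Keys retained in at least ``study_min`` studies."""
    if not per_study_retained:
        raise ValueError("per_study_retained must contain at least one study")
    if study_min < 1:
        raise ValueError("study_min must be >= 1")
    if study_min > len(per_study_retained):
        logger.warning("study_min=%d exceeds the %d available studies; "
                       "no key can be universal", study_min,
                       len(per_study_retained))
        return set()
    counts = Counter(k for s in per_study_retained.values() for k in s)
    return {k for k, c in counts.items() if c >= study_min}


def _project(key: SnvKey, position_only: bool):
    return (key.genome_id, key.position) if position_only else key


def run_meta_analysis(samples, snv_tables: dict[str, list],
                      config: MetaConfig | None = None,
                      endpoint: str = "T1") -> AdaptiveResult:
    """Run the full adaptive-SNV meta-analysis over a multi-study cohort.

    Parameters
    ----------
    samples:
        DataFrame (or records coercible to one) with columns sample_id,
        study, host, arm, timepoint, sequencing_depth. Hosts lacking a
        T0/T1 pair are dropped with a logged count.
    snv_tables:
        Mapping sample_id -> filtered SNV calls for that sample.
    config:
        Thresholds; see :class:`MetaConfig`.

    Returns an :class:`AdaptiveResult` whose ``table`` has one row per
    study-retained candidate with its per-study prevalence, supporting
    studies, null flag and universality call.
    """
    config = config or MetaConfig()
    meta = pd.DataFrame(samples) if not isinstance(samples, pd.DataFrame) \
        else samples.copy()

    # per-sample depth normalization (Eq-style nsnv = count / depth)
    norm_rows = []
    for row in meta.itertuples():
        raw = len(snv_tables.get(row.sample_id, []))
        norm_rows.append(NormalizationResult(
            sample_id=row.sample_id, raw_snv_count=raw,
            sequencing_depth=row.sequencing_depth,
            nsnv=normalize_snv_count(raw, row.sequencing_depth)))
    normalization = pd.DataFrame([vars(r) for r in norm_rows])

    # pair T0/<endpoint> per host
    host_sets: dict[tuple[str, str], set[SnvKey]] = {}
    arms: dict[tuple[str, str], str] = {}
    n_unmatched = 0
    for (study, host), grp in meta.groupby(["study", "host"], sort=True):
        tps = dict(zip(grp.timepoint, grp.sample_id))
        if "T0" not in tps or endpoint not in tps:
            n_unmatched += 1
            continue
        diff = host_differential_snvs(snv_tables.get(tps["T0"], []),
                                      snv_tables.get(tps[endpoint], []))
        host_sets[(study, host)] = diff
        arms[(study, host)] = grp.arm.iloc[0]
    if n_unmatched:
        logger.info("dropped %d hosts without a matched T0/%s pair",
                    n_unmatched, endpoint)

    studies = sorted({s for s, _ in host_sets})
    proj = lambda k: _project(k, config.position_only)

    # stage 2: prevalence within each study over probiotic-arm hosts
    per_study_retained: dict[str, set[SnvKey]] = {}
    per_study_prevalence: dict[str, dict] = {}
    key_instances: dict = defaultdict(set)  # projected -> full keys seen
    for study in studies:
        prob_hosts = {h: s for (st, h), s in host_sets.items()
                      if st == study and arms[(st, h)] == "probiotic"}
        if not prob_hosts:
            per_study_retained[study] = set()
            per_study_prevalence[study] = {}
            continue
        projected = {h: {proj(k) for k in s} for h, s in prob_hosts.items()}
        for s in prob_hosts.values():
            for k in s:
                key_instances[proj(k)].add(k)
        prevalence, retained = prevalence_filter(
            projected, config.prevalence_threshold)
        per_study_retained[study] = retained
        per_study_prevalence[study] = prevalence

    # stage 4 (universality is computed before flagging nulls so the table
    # can report both independently)
    universal_candidates = universality(per_study_retained, config.study_min) \
        if per_study_retained else set()

    # stage 3: control-arm null model
    null_excluded: set = set()
    control_union: set = set()
    if config.null_model == "control-arm":
        control_hosts = {f"{st}/{h}": {proj(k) for k in s}
                         for (st, h), s in host_sets.items()
                         if arms[(st, h)] == "control"}
        if not control_hosts:
            raise ValueError(
                "null model 'control-arm' requested but no study has "
                "control-arm hosts; re-run with null_model='off'")
        all_candidates = set().union(*per_study_retained.values()) \
            if per_study_retained else set()
        _, null_excluded = null_model_exclude(all_candidates, control_hosts)
        for s in control_hosts.values():
            control_union |= s

    universal = universal_candidates - null_excluded

    # assemble the candidate table
    rows = []
    all_keys = sorted(set().union(*per_study_retained.values())
                      if per_study_retained else set(),
                      key=lambda k: (k if not config.position_only else k))
    for pk in all_keys:
        supporting = {st for st, r in per_study_retained.items() if pk in r}
        full = sorted(key_instances.get(pk, {pk}))
        rep = full[0]
        rows.append({
            "genome_id": rep.genome_id if isinstance(rep, SnvKey) else rep[0],
            "position": rep.position if isinstance(rep, SnvKey) else rep[1],
            "from_allele": rep.from_allele if isinstance(rep, SnvKey) else "*",
            "to_allele": rep.to_allele if isinstance(rep, SnvKey) else "*",
            "per_study_prevalence": {
                st: round(p.get(pk, 0.0), 6)
                for st, p in per_study_prevalence.items() if pk in p},
            "supporting_studies": ",".join(sorted(supporting)),
            "n_supporting_studies": len(supporting),
            "null_flag": pk in null_excluded or pk in control_union,
            "universal": pk in universal,
        })
    table = pd.DataFrame(rows, columns=[
        "genome_id", "position", "from_allele", "to_allele",
        "per_study_prevalence", "supporting_studies",
        "n_supporting_studies", "null_flag", "universal"])

    if config.position_only:
        universal_full = set()
        for pk in universal:
            universal_full |= key_instances.get(pk, set())
        universal = universal_full

    return AdaptiveResult(table=table, universal=universal,
                          normalization=normalization,
                          per_study_retained=per_study_retained,
                          null_excluded=null_excluded,
                          n_unmatched_hosts=n_unmatched, config=config)
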