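import pytest
from hypothesis import HealthCheck, settings

from adaptsnv.io import load_table3_fixture
from adaptsnv.simulate import SimConfig, generate_reference, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


#: scenario used throughout: six paired-design studies, two equal arms,
#: five planted universal SNVs (60% of probiotic hosts, three studies),
#: 200 host-private background SNVs per sample
RECOVERY_SIM = dict(n_studies=6, hosts_per_study=10, control_fraction=0.5,
                    n_planted_adaptive=5, planted_prevalence=0.6,
                    planted_study_support=3, n_background_per_host=200)


@pytest.fixture(scope="session")
def table3():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def reference():
    return generate_reference(SimConfig(seed=7))


@pytest.fixture(scope="session")
def cohort():
    """One standard recovery scenario, shared across tests (read-only)."""
    cfg = SimConfig(seed=1, **RECOVERY_SIM)
    return simulate_cohort(cfg, generate_reference(cfg))


def cohort_frames(sim):
    """(metadata DataFrame, snv_tables as SnvCall lists) for run_meta_analysis."""
    import dataclasses

    import pandas as pd

    from adaptsnv.io import SnvCall

    meta = pd.DataFrame([dataclasses.asdict(s) for s in sim.samples])
    tables = {
        sid: [SnvCall(genome_id=sim.reference.genome_id, position=c.position,
                      ref_allele=c.ref_allele, alt_allele=c.alt_allele,
                      quality=c.quality, depth=c.depth, sample_id=sid)
              for c in calls]
        for sid, calls in sim.snv_tables.items()}
    return meta, tables
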