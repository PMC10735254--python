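"""Shared fixtures: small deterministic synthetic runs reused across tests.

The expensive multi-sample pipeline runs are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from herbseq import pipeline, simulate

# Per-section within-divergence targets mirroring the four sections' printed
# mean distances (0.38 %, 0.76 %, 0.9 %, 0.64 %).
SECTION_WITHIN = {
    "Siphonomorpha": 0.0038,
    "Silene": 0.0076,
    "Physolychnis": 0.009,
    "Elisanthe": 0.0064,
}


def study_contamination(specs):
    """A donor->recipient plan injecting 0.03-0.9 % from young donors of a
    different section into each non-donor sample."""
    donors = {
        "Siphonomorpha": "2019_acaulis",
        "Silene": "2019_burchellii",
        "Elisanthe": "2018_noctiflora",
        "Physolychnis": "2017_sachalinensis",
    }
    rate_cycle = [0.0003, 0.002, 0.005, 0.009]
    rates = {}
    i = 0
    for s in specs:
        if s.name in donors.values():
            continue
        donor_section = [sec for sec in donors if sec != s.section][i % 3]
        rates[(donors[donor_section], s.name)] = rate_cycle[i % 4]
        i += 1
    return simulate.ContaminationPlan(rates=rates)


def study_like_config(depth: int = 400, genome_copies: int = 300) -> simulate.SimConfig:
    """Scaled-down study conditions: 12 specimens, 4 sections, 6 loci / 9 kb,
    contamination rates spanning the observed 0.03-0.9 % range."""
    specs = simulate.study_sample_specs(depth=depth, genome_copies=genome_copies)
    return simulate.SimConfig(
        n_loci=6,
        total_length=9000,
        members_per_section=4,
        samples=specs,
        contamination=study_contamination(specs),
    )


@pytest.fixture
def rng():
    # function-scoped so every test sees the same stream regardless of
    # which subset of the suite runs
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def locus_set():
    return simulate.generate_locus_set(6, 9000, 0.4, seed=7)


@pytest.fixture(scope="session")
def section_db(locus_set):
    return simulate.diverge_sections(
        locus_set, n_sections=4, within_divergence=0.007,
        between_divergence=0.055, members_per_section=2, seed=1,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Four samples (two young, one mid-age, one old) with one planted
    cross-contamination edge; the workhorse fixture for stage tests."""
    cfg = simulate.SimConfig(
        n_loci=6, total_length=9000, members_per_section=2,
        samples=[
            simulate.SampleSpec(name="young", section="Siphonomorpha", age=2,
                                depth=300, genome_copies=120, chimera_rate=0.05),
            simulate.SampleSpec(name="donor", section="Physolychnis", age=5,
                                depth=300, genome_copies=120),
            simulate.SampleSpec(name="mid", section="Silene", age=40,
                                depth=300, genome_copies=120),
            simulate.SampleSpec(name="old", section="Elisanthe", age=85,
                                depth=300, genome_copies=120),
        ],
        contamination=simulate.ContaminationPlan(rates={("donor", "young"): 0.01}),
    )
    return simulate.simulate_run(cfg, seed=42)


@pytest.fixture(scope="session")
def study_run():
    """Full pipeline over the 12-specimen study-like configuration."""
    cfg = study_like_config()
    return pipeline.run(pipeline.RunConfig(sim=cfg), seed=7)
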