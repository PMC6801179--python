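"""Shared fixtures: a small synthetic study reused across module tests."""

import pytest

import probioqc.synthetic_data as synth


@pytest.fixture(scope="session")
def config():
    return synth.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def panel(config):
    return synth.make_toy_genomes(config)


@pytest.fixture(scope="session")
def small_panel():
    """A 2-strain panel with short genomes for brute-force oracle tests."""
    cfg = synth.SimulationConfig(seed=11)
    cfg.genome.n_strains = 2
    cfg.genome.genome_length = 2000
    cfg.genome.orf_length = 300
    cfg.genome.orf_gap = 100
    cfg.genome.pair = ("S_thermophilus_BT01", "B_lactis_BI04")
    cfg.genome.indel_length = 54
    return synth.make_toy_genomes(cfg)


@pytest.fixture(scope="session")
def reads_and_assignments(panel):
    import probioqc.metagenome as mg

    cfg = synth.SimulationConfig(seed=7)
    cfg.reads.n_reads = 4000
    cfg.reads.substitution_error_rate = 0.0
    reads = synth.simulate_reads(panel, cfg)
    profile, assignments = mg.profile_reads(reads, panel)
    return reads, profile, assignments
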