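"""Generators: determinism, construction guarantees, truth-label composition."""

import numpy as np
import pytest

import probioqc.synthetic_data as synth


def _count_mismatches_and_gap(a: str, b: str, del_pos: int, del_len: int) -> tuple[int, int]:
    """Exhaustive pairwise comparison given the known deletion placement."""
    assert len(a) - len(b) == del_len
    head_mm = sum(x != y for x, y in zip(a[: del_pos - 1], b[: del_pos - 1]))
    tail_mm = sum(x != y for x, y in zip(a[del_pos - 1 + del_len :], b[del_pos - 1 :]))
    return head_mm + tail_mm, len(a) - len(b)


class TestMakeToyGenomes:
    def test_lengths_forced_by_construction(self):
        cfg = synth.SimulationConfig(seed=1)
        panel = synth.make_toy_genomes(cfg)
        lengths = {sid: len(seq) for sid, seq in panel.sequences.items()}
        ref, alt = panel.pair
        assert lengths[alt] == 20_000 - 54
        assert all(n == 20_000 for sid, n in lengths.items() if sid != alt)

    def test_determinism_byte_identical(self):
        p1 = synth.make_toy_genomes(synth.SimulationConfig(seed=3))
        p2 = synth.make_toy_genomes(synth.SimulationConfig(seed=3))
        assert p1.sequences == p2.sequences
        assert p1.orfs == p2.orfs
        assert p1.diagnostic_loci == p2.diagnostic_loci

    def test_pair_differs_only_at_snps_plus_indel(self, panel):
        ref, alt = panel.pair
        indel = panel.indels[0]
        n_informative = sum(
            1 for loc in panel.diagnostic_loci if len(loc.alleles) > 1
        )
        mm, gap = _count_mismatches_and_gap(
            panel.sequences[ref], panel.sequences[alt], indel.position, indel.length_bp
        )
        assert mm == n_informative
        assert gap == 54

    def test_orfs_tile_at_least_half_of_each_genome(self, panel):
        for sid, seq in panel.sequences.items():
            covered = sum(end - start + 1 for start, end, _ in panel.orfs[sid])
            assert covered >= 0.5 * len(seq)

    def test_frameshift_indel_request_rejected(self):
        cfg = synth.SimulationConfig(seed=1)
        cfg.genome.indel_length = 10
        with pytest.raises(ValueError, match="multiple of 3"):
            synth.make_toy_genomes(cfg)

    def test_snp_positions_inside_orfs_and_clear_of_indel(self, panel):
        indel = panel.indels[0]
        ref = panel.pair[0]
        for loc in panel.diagnostic_loci:
            if len(loc.alleles) < 2:
                continue
            assert abs(loc.position - indel.position) >= indel.length_bp
            assert any(
                s <= loc.position <= e for s, e, _ in panel.orfs[ref]
            )


class TestSimulateReads:
    def test_degenerate_mixture_all_from_one_strain(self, panel):
        cfg = synth.SimulationConfig(seed=5)
        cfg.reads.n_reads = 100
        cfg.reads.abundance = tuple([1.0] + [0.0] * 7)
        reads = synth.simulate_reads(panel, cfg)
        assert set(reads.truth_strain) == {panel.strain_ids()[0]}

    def test_error_free_reads_are_exact_substrings(self, panel):
        cfg = synth.SimulationConfig(seed=6)
        cfg.reads.n_reads = 200
        cfg.reads.substitution_error_rate = 0.0
        reads = synth.simulate_reads(panel, cfg)
        for seq, sid, pos in zip(reads.sequences, reads.truth_strain, reads.truth_position):
            assert panel.sequences[sid][pos - 1 : pos - 1 + len(seq)] == seq

    def test_truth_counts_within_three_binomial_sd(self, panel):
        cfg = synth.SimulationConfig(seed=8)
        cfg.reads.n_reads = 50_000
        reads = synth.simulate_reads(panel, cfg)
        counts = {sid: 0 for sid in panel.strain_ids()}
        for sid in reads.truth_strain:
            counts[sid] += 1
        for sid, frac in zip(panel.strain_ids(), cfg.reads.abundance):
            expected = frac * cfg.reads.n_reads
            sd = np.sqrt(cfg.reads.n_reads * frac * (1 - frac))
            assert abs(counts[sid] - expected) <= 3 * sd + 1

    def test_determinism(self, panel):
        cfg = synth.SimulationConfig(seed=9)
        cfg.reads.n_reads = 50
        r1 = synth.simulate_reads(panel, cfg)
        r2 = synth.simulate_reads(panel, cfg)
        assert r1.sequences == r2.sequences and r1.truth_strain == r2.truth_strain

    def test_read_longer_than_genome_rejected(self, panel):
        cfg = synth.SimulationConfig(seed=1)
        cfg.reads.read_length = 30_000
        with pytest.raises(ValueError, match="read length"):
            synth.simulate_reads(panel, cfg)


class TestSimulateCytometry:
    def test_pure_live_population(self):
        cfg = synth.SimulationConfig(seed=2)
        cfg.cytometry.fractions = (1.0, 0.0, 0.0)
        cfg.cytometry.n_events = 1000
        events = synth.simulate_cytometry(cfg)
        cells = events[events.label != "bead"]
        assert len(cells) == 1000
        assert set(cells.label) == {"live"}

    def test_bead_count_exact(self):
        cfg = synth.SimulationConfig(seed=2)
        cfg.cytometry.bead_count = 10_000
        events = synth.simulate_cytometry(cfg)
        assert (events.label == "bead").sum() == 10_000

    def test_fraction_composition_binomial(self):
        cfg = synth.SimulationConfig(seed=4)
        events = synth.simulate_cytometry(cfg)
        cells = events[events.label != "bead"]
        n = len(cells)
        for name, frac in zip(["live", "damaged", "dead"], cfg.cytometry.fractions):
            observed = (cells.label == name).sum()
            sd = np.sqrt(n * frac * (1 - frac))
            assert abs(observed - n * frac) <= 3 * sd + 1


class TestSimulateCfsePair:
    def test_zero_shift_identical_distributions(self):
        cfg = synth.SimulationConfig(seed=3)
        cfg.cfse.shift_percent = 0.0
        before, after, _, _ = synth.simulate_cfse_pair(cfg)
        np.testing.assert_allclose(before.FL1.to_numpy(), after.FL1.to_numpy())

    def test_event_counts_preserved_across_conditions(self, config):
        tables = synth.simulate_cfse_pair(config)
        assert len({len(t) for t in tables}) == 1

    def test_shifted_fraction_bookkeeping(self):
        cfg = synth.SimulationConfig(seed=5)
        before, after, _, _ = synth.simulate_cfse_pair(cfg)
        positive = after.label == "urease_positive"
        ratio = after.FL1[positive].to_numpy() / before.FL1[positive].to_numpy()
        np.testing.assert_allclose(ratio, 1.6)
        negative_ratio = after.FL1[~positive].to_numpy() / before.FL1[~positive].to_numpy()
        np.testing.assert_allclose(negative_ratio, 1.0)


class TestKineticsAndQpcr:
    def test_noiseless_series_is_perfectly_linear(self):
        cfg = synth.SimulationConfig(seed=1)
        cfg.od.noise_sd_mod = 0.0
        cfg.od.slope_mod_per_min = 9.0
        (series,) = synth.simulate_od_kinetics(cfg)
        fitted = np.polyfit(series.time_s / 60.0, series.od420_mod, 1)
        assert fitted[0] == pytest.approx(9.0, abs=1e-9)
        assert len(series.time_s) == 60
        assert np.all(np.diff(series.time_s) == 30.0)

    def test_zero_slope_gives_flat_series(self):
        cfg = synth.SimulationConfig(seed=1)
        cfg.od.noise_sd_mod = 0.0
        cfg.od.slope_mod_per_min = 0.0
        (series,) = synth.simulate_od_kinetics(cfg)
        assert np.ptp(series.od420_mod) == 0.0

    def test_negative_noise_rejected(self):
        cfg = synth.SimulationConfig(seed=1)
        cfg.od.noise_sd_mod = -1.0
        with pytest.raises(ValueError):
            synth.simulate_od_kinetics(cfg)

    def test_noiseless_ct_arithmetic(self):
        cal = synth.QpcrConfig(slope=-3.32, intercept=38.0, noise_sd=0.0)
        table = synth.simulate_qpcr(cal, [1e6], seed=0)
        assert len(table) == 3  # triplicate
        assert table.ct.iloc[0] == pytest.approx(38.0 - 3.32 * 6, abs=1e-12)

    def test_nonpositive_cells_rejected(self):
        cal = synth.QpcrConfig()
        with pytest.raises(ValueError):
            synth.simulate_qpcr(cal, [0.0], seed=0)

    def test_positive_slope_rejected(self):
        cal = synth.QpcrConfig(slope=3.32)
        with pytest.raises(ValueError):
            synth.simulate_qpcr(cal, [1e6], seed=0)


class TestSimulateLfq:
    def test_truth_set_size_is_configured_fraction(self, panel):
        cfg = synth.SimulationConfig(seed=4)
        matrix, _, _ = synth.simulate_lfq(panel, cfg)
        n = len(matrix)
        assert matrix.true_differential.sum() == round(0.032 * n)

    def test_no_missing_when_rate_zero(self, panel):
        cfg = synth.SimulationConfig(seed=4)
        cfg.lfq.missing_rate = 0.0
        matrix, cols_b, cols_c = synth.simulate_lfq(panel, cfg)
        assert (matrix[cols_b + cols_c].to_numpy() > 0).all()

    def test_config_rate_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.SimulationConfig(seed=1, reads=synth.ReadConfig(abundance=(0.5, 0.4)))
        with pytest.raises(ValueError, match="outside"):
            synth.SimulationConfig(seed=1, lfq=synth.LfqConfig(missing_rate=1.5))
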