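"""Read assignment against a brute-force DP oracle; profile conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import probioqc.metagenome as mg
import probioqc.synthetic_data as synth
from probioqc._align import align_infix, revcomp
from probioqc.synthetic_data import UNASSIGNED


def semiglobal_distance(query: str, target: str) -> int:
    """Independent DP oracle: best edit distance of query placed anywhere
    inside target (free gaps at both target ends)."""
    n, m = len(query), len(target)
    prev = np.zeros(m + 1, dtype=int)  # row 0: free start in target
    for i in range(1, n + 1):
        cur = np.empty(m + 1, dtype=int)
        cur[0] = i
        for j in range(1, m + 1):
            cost = 0 if query[i - 1] == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev.min())


class TestAlignOracle:
    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_infix_distance_matches_dp_oracle(self, data):
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        target = "".join(rng.choice(list("ACGT"), size=200))
        start = int(rng.integers(0, 160))
        read = target[start : start + 40]
        n_mut = int(rng.integers(0, 5))
        chars = list(read)
        for p in rng.choice(len(chars), size=n_mut, replace=False):
            chars[p] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(chars)
        hit = align_infix(read, target)
        assert hit.edit_distance == semiglobal_distance(read, target)

    def test_assign_read_picks_oracle_best_strain(self, small_panel):
        rng = np.random.default_rng(0)
        ids = small_panel.strain_ids()
        for trial in range(10):
            sid = ids[trial % 2]
            genome = small_panel.sequences[sid]
            start = int(rng.integers(0, len(genome) - 60))
            read = genome[start : start + 60]
            asg = mg.assign_read(read, small_panel, min_length=40)
            oracle = {
                s: min(
                    semiglobal_distance(read, small_panel.sequences[s]),
                    semiglobal_distance(revcomp(read), small_panel.sequences[s]),
                )
                for s in ids
            }
            best = min(oracle.values())
            assert oracle[asg.strain_id] == best


class TestAssignRead:
    def test_exact_read_full_identity(self, panel):
        sid = panel.strain_ids()[3]
        read = panel.sequences[sid][5000:5150]
        asg = mg.assign_read(read, panel)
        assert asg.strain_id == sid
        assert asg.identity == 1.0
        assert not asg.tie
        assert (asg.start, asg.end) == (5001, 5150)

    def test_short_read_discarded(self, panel):
        read = panel.sequences[panel.strain_ids()[0]][100:179]  # 79 bp
        asg = mg.assign_read(read, panel)
        assert asg.strain_id == UNASSIGNED
        assert asg.reason == "short"

    def test_identity_below_threshold_unassigned(self, panel):
        sid = panel.strain_ids()[0]
        read = list(panel.sequences[sid][2000:2100])
        for p in (10, 50, 90):  # 3 substitutions in a 100-mer -> identity 0.97
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        asg = mg.assign_read("".join(read), panel)
        assert asg.strain_id == UNASSIGNED
        assert asg.identity == pytest.approx(0.97)

    def test_reverse_complement_read_assigned_forward_coordinates(self, panel):
        sid = panel.strain_ids()[4]
        read = revcomp(panel.sequences[sid][3000:3150])
        asg = mg.assign_read(read, panel)
        assert asg.strain_id == sid
        assert asg.orientation == "-"
        assert (asg.start, asg.end) == (3001, 3150)

    def test_pair_tie_flagged(self, panel):
        ref, alt = panel.pair
        # a window away from SNPs and the indel is identical in both members
        read = panel.sequences[ref][500:650]
        asg = mg.assign_read(read, panel)
        assert asg.tie
        assert set(asg.tied_strains) == {ref, alt}

    def test_non_iupac_characters_rejected(self, panel):
        with pytest.raises(ValueError, match="non-IUPAC"):
            mg.assign_read("ACGT@" * 30, panel)


class TestProfileReads:
    def test_conservation_of_reads(self, reads_and_assignments):
        reads, profile, _ = reads_and_assignments
        assert (
            profile.n_assigned + profile.n_unassigned + profile.n_discarded_short
            == profile.n_reads
            == len(reads)
        )

    def test_abundances_sum_to_one(self, reads_and_assignments):
        _, profile, _ = reads_and_assignments
        assert sum(profile.relative_abundance.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_strain_reads_give_unit_abundance(self, panel):
        cfg = synth.SimulationConfig(seed=13)
        cfg.reads.n_reads = 150
        cfg.reads.abundance = tuple([1.0] + [0.0] * 7)
        cfg.reads.substitution_error_rate = 0.0
        reads = synth.simulate_reads(panel, cfg)
        profile, _ = mg.profile_reads(reads, panel)
        sid = panel.strain_ids()[0]
        assert profile.relative_abundance[sid] == pytest.approx(1.0)

    def test_two_strain_symmetry(self, small_panel):
        a, b = small_panel.strain_ids()
        reads = synth.ReadSet(
            ids=[f"r{i}" for i in range(40)],
            sequences=[small_panel.sequences[a][i * 40 : i * 40 + 100] for i in range(20)]
            + [small_panel.sequences[b][i * 40 : i * 40 + 100] for i in range(20)],
        )
        profile, _ = mg.profile_reads(reads, small_panel)
        assert profile.relative_abundance[a] == pytest.approx(0.5, abs=1e-9)
        assert profile.relative_abundance[b] == pytest.approx(0.5, abs=1e-9)

    def test_raising_min_identity_never_increases_hits(self, panel):
        cfg = synth.SimulationConfig(seed=21)
        cfg.reads.n_reads = 300
        cfg.reads.substitution_error_rate = 0.01
        reads = synth.simulate_reads(panel, cfg)
        loose, _ = mg.profile_reads(reads, panel, min_identity=0.95)
        strict, _ = mg.profile_reads(reads, panel, min_identity=0.99)
        for sid in panel.strain_ids():
            assert strict.total_hit_count[sid] <= loose.total_hit_count[sid] + 1e-9

    def test_zero_hits_yields_undefined_abundance(self, panel):
        rng = np.random.default_rng(99)
        reads = synth.ReadSet(
            ids=["r0"], sequences=["".join(rng.choice(list("ACGT"), size=120))]
        )
        profile, _ = mg.profile_reads(reads, panel)
        assert profile.relative_abundance is None

    def test_distinct_orf_count_mode(self, reads_and_assignments, panel):
        reads, _, assignments = reads_and_assignments
        profile, _ = mg.profile_reads(reads, panel, assignments=assignments,
                                      count_mode="distinct_orfs")
        total = sum(len(panel.orfs[sid]) for sid in panel.strain_ids())
        assert 0 < sum(
            v for v in profile.relative_abundance.values()
        ) == pytest.approx(1.0)
        assert all(
            profile.relative_abundance[sid] >= 0 for sid in panel.strain_ids()
        )


class TestExpectedReadCount:
    def test_blend_coverage_arithmetic(self):
        reads, pct = mg.expected_read_count(1e9, 450e9, 6e6)
        assert reads == pytest.approx(13333.3, abs=0.05)
        assert pct == pytest.approx(0.222, abs=0.0005)

    def test_zero_strain(self):
        reads, pct = mg.expected_read_count(0, 450e9, 6e6)
        assert reads == 0.0 and pct == 0.0

    def test_identity_case(self):
        reads, pct = mg.expected_read_count(5e9, 5e9, 1e6)
        assert reads == 1e6 and pct == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mg.expected_read_count(1e9, 0, 6e6)


AA = "MKVLAGTSDERFNQHYWCPI"


class TestScreenResistome:
    def test_identical_query_full_identity(self):
        ref = AA * 10
        hits = mg.screen_resistome([("q1", ref)], [("tetW_like", ref)])
        assert len(hits) == 1
        assert hits[0].identity == 1.0

    def test_quarter_mutated_query_below_threshold(self):
        rng = np.random.default_rng(5)
        ref = "".join(rng.choice(list(AA), size=200))
        mutated = list(ref)
        for p in rng.choice(200, size=50, replace=False):
            mutated[p] = AA[(AA.index(mutated[p]) + 1) % len(AA)]
        hits = mg.screen_resistome([("q1", "".join(mutated))], [("arg1", ref)])
        assert hits == []

    def test_zero_threshold_reports_every_pair(self):
        hits = mg.screen_resistome(
            [("q1", "MKV"), ("q2", "WWW")],
            [("a1", "MKV"), ("a2", "CCC")],
            min_aa_identity=0.0,
        )
        assert len(hits) == 4
        assert hits == sorted(hits, key=lambda h: -h.identity)

    def test_empty_db_warns(self):
        with pytest.warns(UserWarning, match="empty ARG"):
            assert mg.screen_resistome([("q1", "MKV")], []) == []


class TestCompareIndelAlleles:
    def test_in_frame_deletion(self):
        rng = np.random.default_rng(3)
        gene = "".join(rng.choice(list("ACGT"), size=600))
        shorter = gene[:300] + gene[354:]
        report = mg.compare_indel_alleles(gene, shorter)
        assert report.length_bp == 54
        assert report.in_frame
        assert report.aa_difference == 18
        assert not report.multi_indel

    def test_identical_sequences(self):
        report = mg.compare_indel_alleles("ACGTACGT" * 20, "ACGTACGT" * 20)
        assert report.length_bp == 0 and report.aa_difference == 0

    def test_frameshift_deletion(self):
        rng = np.random.default_rng(4)
        gene = "".join(rng.choice(list("ACGT"), size=400))
        report = mg.compare_indel_alleles(gene, gene[:200] + gene[210:])
        assert report.length_bp == 10
        assert not report.in_frame
        assert report.aa_difference is None

    def test_two_gaps_flagged(self):
        rng = np.random.default_rng(6)
        gene = "".join(rng.choice(list("ACGT"), size=600))
        other = gene[:100] + gene[130:400] + gene[430:]
        report = mg.compare_indel_alleles(gene, other)
        assert report.multi_indel
        assert report.length_bp == 60
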