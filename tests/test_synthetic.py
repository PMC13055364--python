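"""Generator correctness: composition, planting, evolution, mosaics."""

import math

import numpy as np
import pytest

from eve_codiv.orfs import translate
from eve_codiv.synthetic import (FlankSpec, SimulationConfig, evolve_protein,
                                 make_mosaic, make_scaffold,
                                 make_structure_pair, plant_eve,
                                 protein_to_nt, reverse_complement,
                                 simulate_dataset)


class TestMakeScaffold:
    def test_gc_extremes(self):
        assert set(make_scaffold(200, 0.0, 1)) <= {"A", "T"}
        assert set(make_scaffold(200, 100.0, 1)) <= {"G", "C"}

    def test_empirical_gc_within_binomial_band(self):
        s = make_scaffold(100_000, 40.0, 7)
        gc = 100.0 * (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 40.0) < 1.0        # ~6.4 SD at n = 1e5

    def test_deterministic_under_seed(self):
        assert make_scaffold(5000, 35.0, 9) == make_scaffold(5000, 35.0, 9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            make_scaffold(0, 50.0, 1)
        with pytest.raises(ValueError):
            make_scaffold(10, 120.0, 1)


class TestEvolveProtein:
    ROOT = "M" + "ACDEFGHIKLMNPQRSTVWY" * 10

    def test_zero_branch_lengths_keep_root(self):
        tips = evolve_protein(self.ROOT, "((A:0,B:0):0,C:0);", 1.0, 3)
        assert all(s == self.ROOT for s in tips.values())

    def test_rate_zero_keeps_root(self):
        tips = evolve_protein(self.ROOT, "(A:1,B:2,C:3);", 0.0, 3)
        assert all(s == self.ROOT for s in tips.values())

    def test_two_tip_identity_matches_poisson_no_hit_expectation(self):
        # identity per site ~= P(no substitution event on either branch)
        # = exp(-2*bl*rate); reversions contribute O(lambda^2/19)
        bl, rate = 0.05, 1.0
        root = self.ROOT
        idents = []
        for rep in range(400):
            tips = evolve_protein(root, f"(A:{bl},B:{bl});", rate, rep)
            a, b = tips["A"], tips["B"]
            idents.append(np.mean([x == y for x, y in zip(a, b)]))
        expected = math.exp(-2 * bl * rate)
        assert abs(np.mean(idents) - expected) < 0.01

    def test_malformed_newick_raises(self):
        with pytest.raises(Exception):
            evolve_protein(self.ROOT, "((A:1,B:2;", 1.0, 0)


class TestPlantEve:
    def _orf(self, n_codons=240, seed=0):
        rng = np.random.default_rng(seed)
        from eve_codiv.synthetic import _random_protein
        prot = _random_protein(n_codons, rng)
        return prot, protein_to_nt(prot, rng)

    def test_forward_coordinates_exact(self):
        prot, orf = self._orf(233)          # 699 + 3 = 702 nt
        scaffold = make_scaffold(5000, 40.0, 1)
        contig, rec = plant_eve(scaffold, orf, 1000, FlankSpec(), 2)
        assert (rec.orf_start, rec.orf_end, rec.strand) == (1000, 1000 + len(orf), "+")
        assert contig[1000:1000 + len(orf)] == orf
        assert rec.protein == prot

    def test_truth_round_trip_translation(self):
        prot, orf = self._orf(300, seed=5)
        contig, rec = plant_eve(make_scaffold(6000, 40.0, 3), orf, 2000,
                                FlankSpec(), 4)
        extracted = contig[rec.orf_start:rec.orf_end]
        assert translate(extracted, 9).rstrip("*") == rec.protein

    def test_minus_strand_round_trips_under_rc(self):
        prot, orf = self._orf(250, seed=6)
        contig, rec = plant_eve(make_scaffold(6000, 40.0, 3), orf, 2000,
                                FlankSpec(), 4, strand="-")
        assert rec.strand == "-"
        extracted = contig[rec.orf_start:rec.orf_end]
        assert translate(reverse_complement(extracted), 9).rstrip("*") == prot

    def test_rejects_orf_without_start_or_with_internal_stop(self):
        scaffold = make_scaffold(5000, 40.0, 1)
        with pytest.raises(ValueError):
            plant_eve(scaffold, "TTGAAATAA", 1000, FlankSpec(), 2)
        with pytest.raises(ValueError):
            plant_eve(scaffold, "ATG" + "TAA" + "AAATAA", 1000,
                      FlankSpec(), 2)

    def test_flank_gc_regimes_respected(self):
        prot, orf = self._orf(300, seed=8)
        spec = FlankSpec(left_gc=10.0, right_gc=60.0, flank_len=300)
        contig, rec = plant_eve(make_scaffold(6000, 40.0, 3), orf, 2000,
                                spec, 4)
        left = contig[rec.orf_start - 300:rec.orf_start]
        right = contig[rec.orf_end:rec.orf_end + 300]
        gc = lambda s: 100.0 * (s.count("G") + s.count("C")) / len(s)
        # 3 SD of binomial(300, p); guard codon shifts left by < 1 point
        assert abs(gc(left) - 10.0) < 3 * 100 * math.sqrt(0.1 * 0.9 / 300) + 1.1
        assert abs(gc(right) - 60.0) < 3 * 100 * math.sqrt(0.6 * 0.4 / 300)


class TestMakeMosaic:
    A = "AAAAAAAAAA"
    B = "CCCCCCCCCC"

    def test_no_breakpoints_returns_parent_a(self):
        assert make_mosaic(self.A, self.B, []) == self.A

    def test_midpoint_switch(self):
        assert make_mosaic(self.A, self.B, [5]) == "AAAAACCCCC"

    def test_segment_membership_positional_oracle(self):
        bps = [3, 7]
        out = make_mosaic(self.A, self.B, bps)
        for i in range(10):
            n_before = sum(1 for b in bps if b <= i)
            expect = self.A[i] if n_before % 2 == 0 else self.B[i]
            assert out[i] == expect

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            make_mosaic("AAA", "CCCC", [])


class TestMakeStructurePair:
    def test_zero_noise_zero_rmsd(self):
        _, _, rmsd = make_structure_pair(50, 0.0, (10, 20, 30), seed=1)
        assert rmsd < 1e-9

    def test_rotation_only_zero_rmsd(self):
        _, _, rmsd = make_structure_pair(50, 0.0, (90, 0, 0), seed=2)
        assert rmsd < 1e-9

    def test_noisy_rmsd_matches_monte_carlo_mean(self):
        vals = [make_structure_pair(500, 1.0, (15, 25, 35), seed=s)[2]
                for s in range(40)]
        target = make_structure_pair(500, 1.0, (15, 25, 35), seed=99)[2]
        assert abs(target - np.mean(vals)) / np.mean(vals) < 0.10

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            make_structure_pair(2, 0.0, (0, 0, 0), seed=1)


class TestSimulateDataset:
    def test_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(n_species=2, contigs_per_species=1,
                               contig_length=20_000, seed=5)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert d1.contigs == d2.contigs
        assert d1.truth == d2.truth
        d1.write(tmp_path / "a")
        d2.write(tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                g = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == g.read_bytes()

    def test_truth_records_round_trip(self, small_dataset):
        for t in small_dataset.truth:
            nt = small_dataset.contigs[t.contig_id][t.orf_start:t.orf_end]
            if t.strand == "-":
                nt = reverse_complement(nt)
            assert translate(nt, 9).rstrip("*") == t.protein
            assert (t.orf_end - t.orf_start) % 3 == 0

    def test_paralog_groups_have_identical_proteins(self, small_dataset):
        by_group = {}
        for t in small_dataset.truth:
            by_group.setdefault(t.paralog_group, set()).add(t.protein)
        assert all(len(v) == 1 for v in by_group.values())

    def test_ns1_gc_near_configured_target(self, small_dataset):
        cfg = small_dataset.config
        gcs = []
        for t in small_dataset.truth:
            nt = small_dataset.contigs[t.contig_id][t.orf_start:t.orf_end]
            gcs.append(100.0 * (nt.count("G") + nt.count("C")) / len(nt))
        assert abs(np.mean(gcs) - cfg.ns1_gc) < 0.5
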