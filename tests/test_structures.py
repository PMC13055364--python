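"""Kabsch superposition, domain screening, RMSD classification, file IO."""

import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from eve_codiv.structures import (StructureModel, classify_rmsd, kabsch_rmsd,
                                  load_structure, qc_filter,
                                  residue_correspondence, screen_domain,
                                  superpose_pair, walker_a_seeds)
from eve_codiv.synthetic import make_structure_pair


def _chain_model(seq, model_id="m", spacing=3.8, res_ids=None):
    n = len(seq)
    ca = np.zeros((n, 3))
    ca[:, 0] = np.arange(n) * spacing
    return StructureModel(model_id=model_id,
                          residue_ids=np.array(res_ids or range(1, n + 1)),
                          sequence=seq, ca=ca)


class TestKabsch:
    def test_identical_sets_zero(self):
        a = np.random.default_rng(0).normal(size=(20, 3))
        assert kabsch_rmsd(a, a)[0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_rotation_zero(self):
        a = np.random.default_rng(1).normal(size=(20, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        assert kabsch_rmsd(a, a @ R.T)[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_point_analytic_case(self):
        a = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        b = np.array([[2.0, 0, 0], [-2.0, 0, 0]])
        assert kabsch_rmsd(a, b)[0] == pytest.approx(1.0, abs=1e-12)

    def test_rigid_motion_invariance_to_1e9(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(50, 3))
        b = a + rng.normal(scale=0.5, size=(50, 3))
        base = kabsch_rmsd(a, b)[0]
        R = Rotation.from_euler("xyz", [17, -42, 96], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved = kabsch_rmsd(a @ R.T + t, b @ R.T + t)[0]
        assert abs(moved - base) < 1e-9

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(30, 3))
        b = a + rng.normal(scale=1.0, size=(30, 3))
        assert kabsch_rmsd(a, b)[0] == pytest.approx(kabsch_rmsd(b, a)[0],
                                                     abs=1e-9)

    def test_reflection_not_allowed(self):
        # mirrored set: proper rotation cannot undo it, RMSD must stay > 0
        rng = np.random.default_rng(4)
        a = rng.normal(size=(30, 3))
        b = a.copy()
        b[:, 0] *= -1
        assert kabsch_rmsd(a, b)[0] > 0.1

    def test_agrees_with_independent_superimposer(self):
        import biotite.structure as struc
        rng = np.random.default_rng(5)
        a = rng.normal(size=(40, 3)) * 5
        b = a @ Rotation.from_euler("y", 30, degrees=True).as_matrix().T \
            + rng.normal(scale=0.8, size=(40, 3))
        fitted, _ = struc.superimpose(b, a)     # fixed, mobile
        oracle = float(np.sqrt(((fitted - b) ** 2).sum(axis=1).mean()))
        # biotite computes in float32; agreement to its precision
        assert kabsch_rmsd(a, b)[0] == pytest.approx(oracle, abs=1e-5)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((1, 3)), np.zeros((1, 3)))

    def test_generator_truth_consistency(self):
        a, b, truth = make_structure_pair(100, 0.0, (20, 30, 40), seed=6)
        assert kabsch_rmsd(a, b)[0] == pytest.approx(truth, abs=1e-6)
        assert truth < 1e-6


class TestClassifyRmsd:
    @pytest.mark.parametrize("rmsd,label", [
        (0.271, "highly_similar"),
        (2.446, "moderately_similar"),
        (2.0, "highly_similar"),          # band boundary is inclusive
        (3.0, "moderately_similar"),
        (3.0001, "significantly_divergent"),
        (36.725, "significantly_divergent"),
    ])
    def test_bands(self, rmsd, label):
        assert classify_rmsd(rmsd) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_rmsd(-0.1)


class TestQcFilter:
    def _m(self, ptm, iptm):
        m = _chain_model("MKV")
        m.ptm, m.iptm = ptm, iptm
        return m

    def test_confident_model_kept(self):
        assert len(qc_filter([self._m(0.6, 0.9)])) == 1

    def test_threshold_is_strict(self):
        assert qc_filter([self._m(0.5, 0.9)]) == []
        assert qc_filter([self._m(0.6, 0.8)]) == []

    def test_missing_metadata_retained_with_warning(self):
        with pytest.warns(UserWarning):
            kept = qc_filter([self._m(None, None)])
        assert len(kept) == 1


class TestCorrespondence:
    def test_identical_sequences_identity_mapping(self):
        a = _chain_model("MKVLAWGH", "a")
        b = _chain_model("MKVLAWGH", "b")
        assert residue_correspondence(a, b) == [(i, i) for i in range(8)]

    def test_internal_deletion_skipped(self):
        a = _chain_model("MKVLAWGH", "a")
        b = _chain_model("MKVAWGH", "b")    # L deleted
        pairs = residue_correspondence(a, b)
        ia = [p[0] for p in pairs]
        assert 3 not in ia                   # the deleted position is unpaired
        assert len(pairs) == 7

    def test_empty_model_raises(self):
        a = _chain_model("MKV")
        with pytest.raises(Exception):
            residue_correspondence(a, StructureModel(
                "e", np.array([], dtype=int), "", np.zeros((0, 3))))


class TestScreenDomain:
    def test_linear_chain_captures_adjacent_residues(self):
        m = _chain_model("A" * 20, spacing=3.8)
        got = screen_domain(m, [10], cutoff=5.0)
        assert got == [9, 10, 11]

    def test_cutoff_zero_keeps_seeds_only(self):
        m = _chain_model("A" * 10)
        assert screen_domain(m, [4, 5], cutoff=0.0) == [4, 5]

    def test_isolated_seed_survives_pruning(self):
        m = _chain_model("A" * 10, spacing=50.0)   # nothing within 5 A
        assert screen_domain(m, [7], cutoff=5.0) == [7]

    def test_short_nonseed_runs_pruned(self):
        # residues 1..5 contiguous near seed; residue 20 isolated non-seed
        n = 21
        ca = np.zeros((n, 3))
        ca[:, 0] = np.arange(n) * 3.8
        ca[19] = ca[2] + np.array([0.0, 4.0, 0.0])   # near seed spatially
        m = StructureModel("m", np.arange(1, n + 1), "A" * n, ca)
        got = screen_domain(m, [3], cutoff=5.0)
        assert 20 not in got                          # run of 1, no seed

    def test_empty_seed_raises(self):
        with pytest.raises(ValueError):
            screen_domain(_chain_model("AAAA"), [])


class TestWalkerA:
    def test_motif_found(self):
        m = _chain_model("MAAGPSGTGKTAAA")
        seeds = walker_a_seeds(m)
        # motif GPSGTGKT spans 0-based 3..10, i.e. residue ids 4..11
        assert seeds == list(range(4, 12))

    def test_no_motif(self):
        assert walker_a_seeds(_chain_model("MAAAAA")) == []


class TestEndToEnd:
    def test_pdb_round_trip_and_superposition(self, tmp_path):
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        seq3 = ["MET", "LYS", "VAL", "LEU", "ALA", "TRP", "GLY", "HIS"]
        rng = np.random.default_rng(9)
        coords = np.cumsum(rng.normal(size=(8, 3)), axis=0) * 2 + 10

        def write(path, xyz, ptm):
            atoms = struc.AtomArray(8)
            atoms.coord = xyz
            atoms.chain_id[:] = "A"
            atoms.res_id[:] = np.arange(1, 9)
            atoms.res_name[:] = seq3
            atoms.atom_name[:] = "CA"
            atoms.element[:] = "C"
            f = pdb.PDBFile()
            f.set_structure(atoms)
            f.write(str(path))
            path.with_suffix(".json").write_text(
                json.dumps({"ptm": ptm, "iptm": 0.9}))

        R = Rotation.from_euler("x", 45, degrees=True).as_matrix()
        write(tmp_path / "a.pdb", coords, 0.8)
        write(tmp_path / "b.pdb", coords @ R.T + 3.0, 0.7)
        a = load_structure(tmp_path / "a.pdb")
        b = load_structure(tmp_path / "b.pdb")
        assert a.sequence == "MKVLAWGH"
        assert a.ptm == 0.8
        res = superpose_pair(a, b)
        assert res.n_pairs == 8
        # PDB files carry 3 coordinate decimals, so ~1e-3 round-trip noise
        assert res.global_rmsd == pytest.approx(0.0, abs=5e-3)
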