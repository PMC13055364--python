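"""Identity matrices, alignment trimming, and ICTV demarcation calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from conftest import gotoh_global
from eve_codiv.distances import (IdentityMatrix, build_matrix, classify_pair,
                                 flag_novel, global_align, pairwise_identity,
                                 trim_columns)
from eve_codiv.synthetic import evolve_protein, _random_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestGlobalAlign:
    def test_identical_sequences_align_gaplessly(self):
        ga, gb = global_align("MKVLAW", "MKVLAW")
        assert ga == gb == "MKVLAW"

    def test_single_deletion_column(self):
        ga, gb = global_align("MKV", "MV")
        assert (ga, gb) == ("MKV", "M-V")

    def test_matches_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(2)
        from eve_codiv.search import ScoringScheme
        scheme = ScoringScheme(gap_open=-10.0, gap_extend=-0.2)
        for _ in range(40):
            n, m = rng.integers(2, 13, size=2)
            a = "".join(AA[i] for i in rng.integers(20, size=n))
            b = "".join(AA[i] for i in rng.integers(20, size=m))
            got = scheme.aligner("global").align(a, b).score
            assert got == pytest.approx(gotoh_global(a, b), abs=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            global_align("", "MK")


class TestPairwiseIdentity:
    def test_identical_pair(self):
        assert pairwise_identity("M" * 100, "M" * 100) == 100.0

    def test_one_mismatch_in_100(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert pairwise_identity(a, b) == 99.0

    def test_gaps_count_as_differences(self):
        # 90 matches, 5 mismatches, 5 residue-vs-gap columns -> 90/100
        a = "A" * 95 + "R" * 5
        b = "A" * 90 + "C" * 5 + "-" * 5
        assert pairwise_identity(a, b) == 90.0

    def test_dual_gap_columns_excluded(self):
        assert pairwise_identity("AA--", "AA--") == 100.0

    def test_ignore_gaps_mode(self):
        a = "AAAR-"
        b = "AAA-C"
        assert pairwise_identity(a, b, ignore_gaps=True) == 100.0

    def test_all_gap_pair_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("--", "--")


class TestBuildMatrix:
    def test_identical_sequences_all_100(self):
        seq = "M" + "ACDEFGHIKLMNPQRSTVWY" * 20
        m = build_matrix({"a": seq, "b": seq, "c": seq})
        assert np.allclose(m.values, 100.0)

    def test_length_filter_boundary(self):
        s400 = "M" * 400
        s399 = "M" * 399
        with pytest.raises(ValueError):
            build_matrix({"a": s400, "b": s399})
        m = build_matrix({"a": s400, "b": s399, "c": s400})
        assert m.labels == ["a", "c"]

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(5)
        prots = {f"s{i}": _random_protein(420, rng) for i in range(4)}
        m = build_matrix(prots)
        assert np.allclose(m.values, m.values.T, atol=1e-9)
        assert np.allclose(np.diag(m.values), 100.0)

    def test_identity_decreases_with_tree_distance(self):
        # rank correlation between patristic distance and (100 - identity)
        import dendropy
        newick = ("(((t1:0.05,t2:0.05):0.1,(t3:0.08,t4:0.07):0.12):0.1,"
                  "((t5:0.06,t6:0.09):0.15,(t7:0.3,t8:0.25):0.05):0.1);")
        root = _random_protein(450, np.random.default_rng(7))
        tips = evolve_protein(root, newick, 1.0, 11)
        m = build_matrix(tips, min_len=100)
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        dists, divs = [], []
        for i, a in enumerate(m.labels):
            for b in m.labels[i + 1:]:
                dists.append(pdm.patristic_distance(taxa[a], taxa[b]))
                divs.append(100.0 - m.identity(a, b))
        rho = spearmanr(dists, divs).statistic
        assert rho > 0.8


class TestClassifyPair:
    @pytest.mark.parametrize("identity,coverage,level", [
        (90.0, 85.0, "same_species"),
        (86.0, 70.0, "same_genus"),      # coverage fails the species rule
        (85.0, 95.0, "same_genus"),      # strict > on identity
        (90.0, 80.0, "same_genus"),      # strict > on coverage
        (35.0, 95.0, "same_genus"),      # genus floor inclusive
        (34.9, 95.0, "distinct"),
        (30.0, 95.0, "distinct"),
        (0.0, 0.0, "distinct"),
        (100.0, 100.0, "same_species"),
    ])
    def test_threshold_truth_table(self, identity, coverage, level):
        assert classify_pair(identity, coverage).level == level

    @settings(max_examples=80, derandomize=True)
    @given(st.floats(0, 100), st.floats(0, 100),
           st.floats(0.1, 14.9))
    def test_raising_identity_never_demotes(self, identity, coverage, bump):
        rank = {"distinct": 0, "same_genus": 1, "same_species": 2}
        lo = classify_pair(identity, coverage).level
        hi = classify_pair(min(identity + bump, 100.0), coverage).level
        assert rank[hi] >= rank[lo]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify_pair(120.0, 50.0)


class TestFlagNovel:
    def _matrix(self, focal_row):
        labels = ["focal", "x", "y"]
        vals = np.full((3, 3), 100.0)
        vals[0, 1] = vals[1, 0] = focal_row[0]
        vals[0, 2] = vals[2, 0] = focal_row[1]
        vals[1, 2] = vals[2, 1] = 90.0
        return IdentityMatrix(labels, vals, [0, 1, 2])

    def test_identical_member_not_novel(self):
        novel, mx = flag_novel(self._matrix([100.0, 60.0]), "focal")
        assert not novel and mx == 100.0

    def test_distant_member_flagged(self):
        novel, mx = flag_novel(self._matrix([60.0, 55.0]), "focal")
        assert novel and mx == 60.0

    def test_boundary_75_not_novel(self):
        novel, _ = flag_novel(self._matrix([75.0, 20.0]), "focal")
        assert not novel

    def test_absent_focal_raises(self):
        with pytest.raises(KeyError):
            flag_novel(self._matrix([50.0, 50.0]), "zzz")


class TestTrimColumns:
    def test_hand_built_alignment(self):
        # modal non-gap frequency per column: c0 A 4/4 keep, c1 A 3/4 keep,
        # c2 all distinct 1/4 drop, c3 C=A 2/4 keep (ties at 50%),
        # c4 A/G/T 1/3 over non-gap rows drop, c5 K 4/4 keep
        msa = ["AAWCAK",
               "AACCGK",
               "AAYA-K",
               "ACVATK"]
        trimmed = trim_columns(msa, min_consensus=50.0)
        assert trimmed == ["AACK", "AACK", "AAAK", "ACAK"]

    def test_conserved_column_retained(self):
        assert trim_columns(["A", "A", "A"]) == ["A", "A", "A"]

    def test_diverse_column_dropped(self):
        msa = [c for c in "ACDEFGHIKLMNPQRSTVWY"]
        assert trim_columns(msa) == [""] * 20

    def test_empty_alignment_raises(self):
        with pytest.raises(ValueError):
            trim_columns([])
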