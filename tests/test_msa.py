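"""Progressive alignment, trimming, category distances, UPGMA, clustering."""

import numpy as np
import pytest

from oracles import biopython_global_score
from stcmine.core import AMINO_ACIDS, PipelineConfig, ProteinRecord, UNCLASSIFIED
from stcmine.msa import (
    DistanceMatrix,
    Msa,
    assign_clades_by_clustering,
    category_distance,
    kmer_distance,
    progressive_align,
    trim_msa,
    upgma,
)
from stcmine.similarity import blosum62
from stcmine._kernels import nw_affine_profile


def rec(pid, seq):
    return ProteinRecord(id=pid, sequence=seq)


def rand_seq(rng, n):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        seqs = [rec(f"s{i}", "ACDEFGHIKL") for i in range(5)]
        msa = progressive_align(seqs)
        assert msa.column_count == 10
        assert all(row == "ACDEFGHIKL" for row in msa.rows)

    def test_single_sequence_gives_trivial_alignment(self):
        msa = progressive_align([rec("s", "ACDEF")])
        assert msa.rows == ["ACDEF"]

    def test_two_sequences_equal_global_dp_score(self):
        rng = np.random.default_rng(13)
        from stcmine.msa import _b62_scaled, _encode_block, _profile_counts

        for _ in range(30):
            a, b = rand_seq(rng, int(rng.integers(3, 11))), rand_seq(
                rng, int(rng.integers(3, 11))
            )
            S = (
                _profile_counts(_encode_block([a]))
                @ _b62_scaled()
                @ _profile_counts(_encode_block([b])).T
            )
            score, _, _ = nw_affine_profile(S, 2.3, 0.63)
            assert score == pytest.approx(biopython_global_score(a, b)), (a, b)

    def test_degapping_rows_reproduces_inputs(self, small_dataset):
        seqs = small_dataset.proteome[:12]
        msa = progressive_align(seqs)
        for i, s in enumerate(seqs):
            assert msa.degapped(i) == s.sequence

    def test_planted_family_aligns_tightly(self):
        from stcmine.simulate import make_clade_model, sample_family

        model = make_clade_model(2, 300 + 36, 12.0, seed=41)
        seqs = sample_family(model, 12, 1.0, seed=42)
        msa = progressive_align(seqs)
        # low-indel family (1% per node): inserts add few extra columns
        # and overall gap content stays small
        assert msa.column_count <= 400
        assert msa.column_gap_fractions().mean() < 0.15
        # trimming the sparse insert columns recovers ~the planted length
        trimmed = trim_msa(msa)
        assert 320 <= trimmed.column_count <= 350


class TestTrim:
    def test_boundary_gap_fraction_kept(self):
        msa = Msa(ids=list("abcd"), rows=["A-", "A-", "AC", "AC"])
        trimmed = trim_msa(msa, gap_threshold=0.5)
        assert trimmed.column_count == 2  # 2/4 gaps == 0.5 is kept

    def test_majority_gap_column_removed(self):
        msa = Msa(ids=list("abcd"), rows=["A-", "A-", "A-", "AC"])
        trimmed = trim_msa(msa, gap_threshold=0.5)
        assert trimmed.rows == ["A", "A", "A", "A"]

    def test_gap_free_alignment_unchanged_and_idempotent(self):
        msa = Msa(ids=list("ab"), rows=["ACD", "AWD"])
        once = trim_msa(msa)
        assert once.rows == msa.rows
        assert trim_msa(once).rows == once.rows

    def test_lower_threshold_keeps_subset_of_columns(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(6):
            rows.append(
                "".join(
                    "-" if rng.random() < 0.4 else AMINO_ACIDS[rng.integers(0, 20)]
                    for _ in range(40)
                )
            )
        msa = Msa(ids=[f"s{i}" for i in range(6)], rows=rows)
        prev_cols = None
        for thr in (0.9, 0.5, 0.2):
            try:
                cols = trim_msa(msa, thr).column_count
            except ValueError:
                cols = 0
            if prev_cols is not None:
                assert cols <= prev_cols
            prev_cols = cols

    def test_fully_trimmed_raises(self):
        msa = Msa(ids=list("ab"), rows=["A-", "-C"])
        with pytest.raises(ValueError, match="fully trimmed"):
            trim_msa(msa, gap_threshold=0.2)


class TestCategoryDistance:
    def test_identical_rows_distance_zero(self):
        msa = Msa(ids=list("ab"), rows=["CMW", "CMW"])
        assert category_distance(msa).values[0, 1] == 0.0

    def test_same_category_substitution_costs_half(self):
        # M and V are both in the {M,V,L,I} category
        msa = Msa(ids=list("ab"), rows=["CM", "CV"])
        d = category_distance(msa).values[0, 1]
        assert d == pytest.approx(-np.log(0.75))  # D = (0 + 0.5)/2

    def test_saturated_pair_capped(self):
        msa = Msa(ids=list("ab"), rows=["CC", "WW"])
        assert category_distance(msa).values[0, 1] == 10.0

    def test_x_is_always_a_full_difference(self):
        msa = Msa(ids=list("ab"), rows=["CX", "CX"])
        assert category_distance(msa).values[0, 1] == pytest.approx(-np.log(0.5))

    def test_disjoint_rows_capped_with_warning(self, caplog):
        msa = Msa(ids=list("ab"), rows=["A-", "-C"])
        with caplog.at_level("WARNING"):
            d = category_distance(msa).values[0, 1]
        assert d == 10.0
        assert "no aligned residues" in caplog.text

    def test_symmetric_zero_diagonal(self, small_dataset):
        seqs = small_dataset.proteome[:8]
        dm = category_distance(trim_msa(progressive_align(seqs)))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(dm)
        assert tree.height == pytest.approx(0.2)
        assert sorted(tree.leaves()) == ["a", "b"]

    def test_three_leaf_hand_example(self):
        values = np.array(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]
        )
        tree = upgma(DistanceMatrix(ids=["A", "B", "C"], values=values))
        assert tree.height == pytest.approx(0.3)
        inner = next(c for c in tree.children if not c.is_leaf)
        assert sorted(inner.leaves()) == ["A", "B"]
        assert inner.height == pytest.approx(0.1)

    def test_topology_invariant_under_input_permutation(self):
        rng = np.random.default_rng(9)
        n = 7
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        ids = [f"leaf{i}" for i in range(n)]

        def signature(node):
            if node.is_leaf:
                return node.leaf_id
            return tuple(sorted((signature(c) for c in node.children), key=repr))

        base = signature(upgma(DistanceMatrix(ids=ids, values=v)))
        perm = rng.permutation(n)
        shuffled = DistanceMatrix(
            ids=[ids[p] for p in perm], values=v[np.ix_(perm, perm)]
        )
        assert signature(upgma(shuffled)) == base

    def test_cophenetic_distances_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            v = rng.random((n, n)) + 0.01
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0.0)
            ids = [f"l{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(ids=ids, values=v))

            heights = {}

            def fill(node):
                if node.is_leaf:
                    return
                left, right = node.children
                for a in left.leaves():
                    for b in right.leaves():
                        heights[tuple(sorted((a, b)))] = 2 * node.height
                fill(left)
                fill(right)

            fill(tree)
            Z = linkage(squareform(v), method="average")
            ref = squareform(cophenet(Z))
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((ids[i], ids[j])))
                    assert heights[key] == pytest.approx(ref[i, j]), (i, j)

    def test_heights_nondecreasing_toward_root(self, small_dataset):
        seqs = small_dataset.proteome[:10]
        dm = category_distance(trim_msa(progressive_align(seqs)))
        tree = upgma(dm)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree)


class TestKmerDistance:
    def test_identical_sequences_distance_zero(self):
        assert kmer_distance("ACDEFGH", "ACDEFGH") == 0.0

    def test_disjoint_sequences_distance_one(self):
        assert kmer_distance("AAAAAA", "WWWWWW") == 1.0


class TestAssignClades:
    def _refs(self, ds):
        return ds.references, ds.ref_clades

    def test_close_candidate_joins_reference_clade(self, small_dataset):
        ds = small_dataset
        clade_of = dict(zip(ds.truth.protein_id, ds.truth.clade))
        cands = [r for r in ds.proteome if clade_of[r.id] == 3][:4]
        calls = assign_clades_by_clustering(cands, *self._refs(ds))
        assert all(c.clade == 3 for c in calls)
        assert all(c.evidence == "distance_cluster" for c in calls)

    def test_missing_reference_clade_raises(self, small_dataset):
        ds = small_dataset
        refs = [r for r in ds.references if ds.ref_clades[r.id] != 2]
        clades = {k: v for k, v in ds.ref_clades.items() if v != 2}
        with pytest.raises(ValueError, match=r"clades \[2\]"):
            assign_clades_by_clustering(ds.proteome[:2], refs, clades)

    def test_never_assigns_a_clade_absent_from_references(self, small_dataset):
        ds = small_dataset
        calls = assign_clades_by_clustering(
            list(ds.proteome[:20]), *self._refs(ds)
        )
        ref_clades = set(ds.ref_clades.values())
        for c in calls:
            assert c.clade == UNCLASSIFIED or c.clade in ref_clades

    def test_mixed_cluster_gives_unclassified(self):
        # two identical references with different labels force ambiguity
        rng = np.random.default_rng(31)
        base = rand_seq(rng, 60)
        refs = [rec("r1", base), rec("r2", base)]
        other = {
            "r3": rand_seq(rng, 60),
            "r4": rand_seq(rng, 60),
        }
        refs += [rec(k, v) for k, v in other.items()]
        ref_clades = {"r1": 1, "r2": 2, "r3": 3, "r4": 4}
        cand = rec("c", base[:30] + rand_seq(rng, 2) + base[32:])
        calls = assign_clades_by_clustering([cand], refs, ref_clades)
        assert calls[0].clade == UNCLASSIFIED
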