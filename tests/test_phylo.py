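"""Jukes-Cantor correction, UPGMA, threshold cuts, bootstrap supports."""

import itertools
import math

import numpy as np
import pytest

from notchkit.align import MultipleAlignment
from notchkit.distmat import DistanceMatrix
from notchkit.phylo import (
    auto_threshold,
    bootstrap_support,
    cut_tree,
    jc_protein_distance,
    merge_heights,
    msa_distance_matrix,
    specialized_phylogeny,
    upgma,
)
from notchkit.records import SequenceRecord
from notchkit.simulate import make_partition_benchmark
from notchkit.tree import TreeNode, leaf


# ---------------------------------------------------------------------------
# Jukes-Cantor
# ---------------------------------------------------------------------------

class TestJCProtein:
    def test_zero(self):
        assert jc_protein_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_protein_distance(0.1) == pytest.approx(0.10566, abs=5e-6)

    def test_saturation_errors(self):
        with pytest.raises(ValueError, match="saturat"):
            jc_protein_distance(0.95)
        with pytest.raises(ValueError):
            jc_protein_distance(-0.01)

    def test_grid_matches_formula_and_dominates_p(self):
        grid = np.linspace(0.0, 0.94, 100)
        d = jc_protein_distance(grid)
        want = -(19 / 20) * np.log(1 - 20 * grid / 19)
        assert np.allclose(d, want, atol=1e-12)
        assert np.all(d[1:] > grid[1:])  # correction strictly exceeds p
        assert np.all(np.diff(d) > 0)  # strictly increasing


# ---------------------------------------------------------------------------
# distance matrices from alignments
# ---------------------------------------------------------------------------

class TestMSADistances:
    def test_identical_rows_are_zero(self):
        msa = MultipleAlignment(["a", "b"], ["ACDE", "ACDE"])
        dm = msa_distance_matrix(msa, kind="p_distance")
        assert dm.values[0, 1] == 0.0

    def test_pairwise_deletion_uses_comparable_columns_only(self):
        msa = MultipleAlignment(["a", "b"], ["AC-E", "ACDE"])
        dm = msa_distance_matrix(msa, kind="p_distance")
        assert dm.values[0, 1] == 0.0  # 3 comparable columns, all equal
        msa2 = MultipleAlignment(["a", "b"], ["AC-E", "ACDF"])
        assert msa_distance_matrix(msa2, kind="p_distance").values[0, 1] == (
            pytest.approx(1 / 3)
        )

    def test_jc_matrix_equals_entrywise_scalar_correction(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAC", "AACCAAAAAA"]
        msa = MultipleAlignment(["x", "y", "z"], rows)
        p = msa_distance_matrix(msa, kind="p_distance").values
        d = msa_distance_matrix(msa, kind="jc_protein").values
        for i, j in itertools.combinations(range(3), 2):
            assert d[i, j] == pytest.approx(jc_protein_distance(p[i, j]))

    def test_incomparable_pair_errors_with_names(self):
        msa = MultipleAlignment(["left", "right"], ["A-", "-C"])
        with pytest.raises(ValueError, match="left.*right"):
            msa_distance_matrix(msa)

    def test_saturated_pair_errors_and_clamps(self):
        rows = ["A" * 40, "C" * 40, "A" * 39 + "C"]
        msa = MultipleAlignment(["a", "b", "c"], rows)
        with pytest.raises(ValueError, match="saturated"):
            msa_distance_matrix(msa, kind="jc_protein")
        dm = msa_distance_matrix(msa, kind="jc_protein", clamp_saturated=True)
        assert np.isfinite(dm.values).all()


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def _brute_force_upgma(labels, matrix):
    """Oracle: rescan the ORIGINAL matrix each step, averaging over all
    member leaves, ties to the smallest (i, j) in current cluster order."""
    original = {
        (a, b): matrix[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
    }
    clusters = [(label, (label,)) for label in labels]  # (name, members)
    merges = []
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                mi, mj = clusters[i][1], clusters[j][1]
                d = sum(original[(a, b)] for a in mi for b in mj) / (
                    len(mi) * len(mj)
                )
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i][1]), frozenset(clusters[j][1])))
        heights.append(d / 2)
        merged = (clusters[i][0], clusters[i][1] + clusters[j][1])
        clusters[i] = merged
        del clusters[j]
    return merges, heights


def _tree_merges(tree):
    out = []
    for node in tree.postorder():
        if not node.is_leaf:
            a, b = node.children
            out.append(
                (node.height, frozenset(a.leaf_names()), frozenset(b.leaf_names()))
            )
    out.sort(key=lambda t: t[0])
    return out


class TestUPGMA:
    def test_hand_run_three_taxa(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]])
        )
        tree = upgma(dm)
        assert tree.height == 2.0
        inner = [n for n in tree.postorder() if not n.is_leaf and n is not tree][0]
        assert inner.height == 1.0
        assert inner.leaf_set() == frozenset({"A", "B"})

    def test_two_taxa_root_at_half_distance(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 3.0], [3.0, 0]]))
        assert upgma(dm).height == 1.5

    def test_equal_distances_tie_rule_gives_caterpillar(self):
        n = 4
        m = np.ones((n, n)) - np.eye(n)
        tree = upgma(DistanceMatrix(list("ABCD"), m))
        assert all(
            node.height == pytest.approx(0.5)
            for node in tree.postorder() if not node.is_leaf
        )
        # ties resolve to smallest (i, j): A+B first, then (AB)+C, then +D
        merges = [frozenset(n.leaf_set()) for n in tree.postorder() if not n.is_leaf]
        assert frozenset("AB") in merges and frozenset("ABC") in merges

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for trial in range(60):
            n = int(rng.integers(2, 7))
            m = np.round(rng.random((n, n)) * 3, 3)
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, m))
            merges, heights = _brute_force_upgma(labels, m)
            got = _tree_merges(tree)
            assert len(got) == len(merges)
            for (h, sa, sb), (oa, ob), oh in zip(got, merges, heights):
                assert {sa, sb} == {oa, ob}
                assert h == pytest.approx(oh)

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(29)
        n = 8
        m = rng.random((n, n)) * 2
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], m))
        z = average(squareform(m, checks=False))
        assert np.allclose(sorted(merge_heights(tree)), sorted(z[:, 2] / 2))

    def test_output_is_ultrametric_and_reproduces_ultrametric_input(self):
        rng = np.random.default_rng(37)
        # build a random ultrametric matrix from a random UPGMA tree
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(6)]
        tree = upgma(DistanceMatrix(labels, m))
        assert tree.is_ultrametric()
        ultra = tree.tip_distances()
        n = len(labels)
        um = np.zeros((n, n))
        for (a, b), v in ultra.items():
            i, j = labels.index(a), labels.index(b)
            um[i, j] = um[j, i] = v
        tree2 = upgma(DistanceMatrix(labels, um))
        back = tree2.tip_distances()
        for pair, v in ultra.items():
            assert back[pair] == pytest.approx(v, abs=1e-9)


# ---------------------------------------------------------------------------
# cutting and auto threshold
# ---------------------------------------------------------------------------

def _toy_tree():
    ab = TreeNode(children=[leaf("A"), leaf("B")], height=1.0)
    return TreeNode(children=[ab, leaf("C")], height=2.0)


class TestCutTree:
    def test_above_root_single_cluster(self):
        clus = cut_tree(_toy_tree(), 5.0)
        assert clus.n_clusters == 1

    def test_toy_cut_between_merges(self):
        clus = cut_tree(_toy_tree(), 1.5)
        assert sorted(map(tuple, clus.clusters)) == [("A", "B"), ("C",)]

    def test_zero_height_gives_singletons(self):
        clus = cut_tree(_toy_tree(), 0.0)
        assert clus.n_clusters == 3

    def test_every_label_assigned_once(self):
        clus = cut_tree(_toy_tree(), 1.5)
        assert sorted(clus.assignments) == ["A", "B", "C"]


class TestAutoThreshold:
    def _chain(self, heights):
        node = leaf("L0")
        for k, h in enumerate(heights):
            node = TreeNode(children=[node, leaf(f"L{k + 1}")], height=h)
        return node

    def test_midpoint_of_largest_gap(self):
        assert auto_threshold(self._chain([1.0, 2.0, 10.0])) == 6.0

    def test_tie_takes_lowest_gap(self):
        assert auto_threshold(self._chain([1.0, 2.0, 3.0])) == 1.5

    def test_requires_three_leaves(self):
        with pytest.raises(ValueError):
            auto_threshold(TreeNode(children=[leaf("A"), leaf("B")], height=1.0))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _aligned_msa(records):
    return MultipleAlignment([r.id for r in records], [r.residues for r in records])


class TestBootstrap:
    def test_clean_split_has_full_support(self):
        records, _ = make_partition_benchmark(
            2, members_per_clade=4, length=300, within=0.02, between=0.4, seed=1
        )
        tree = bootstrap_support(_aligned_msa(records), n_replicates=100, seed=1)
        clades = {
            n.leaf_set(): n.support for n in tree.postorder() if not n.is_leaf
        }
        for side in ({f"K0_{i}" for i in range(4)}, {f"K1_{i}" for i in range(4)}):
            assert clades[frozenset(side)] == 100.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        records, _ = make_partition_benchmark(3, members_per_clade=3, seed=5)
        tree = bootstrap_support(_aligned_msa(records), n_replicates=1, seed=2)
        supports = {n.support for n in tree.postorder() if not n.is_leaf}
        assert supports <= {0.0, 100.0}

    def test_row_permutation_leaves_supports_unchanged(self):
        records, _ = make_partition_benchmark(2, members_per_clade=3, seed=8)
        msa = _aligned_msa(records)
        perm = MultipleAlignment(list(reversed(msa.ids)), list(reversed(msa.rows)))
        t1 = bootstrap_support(msa, n_replicates=25, seed=3)
        t2 = bootstrap_support(perm, n_replicates=25, seed=3)
        s1 = {n.leaf_set(): n.support for n in t1.postorder() if not n.is_leaf}
        s2 = {n.leaf_set(): n.support for n in t2.postorder() if not n.is_leaf}
        assert s1 == s2

    def test_same_seed_reproducible(self):
        records, _ = make_partition_benchmark(3, members_per_clade=3, seed=4)
        msa = _aligned_msa(records)
        t1 = bootstrap_support(msa, n_replicates=20, seed=11)
        t2 = bootstrap_support(msa, n_replicates=20, seed=11)
        assert t1.newick(with_supports=True) == t2.newick(with_supports=True)


# ---------------------------------------------------------------------------
# specialized (consensus-level) phylogeny
# ---------------------------------------------------------------------------

class TestSpecializedPhylogeny:
    def test_two_clusters_of_identical_sequences(self):
        a = MultipleAlignment(["a1", "a2"], ["MKVLWAAL", "MKVLWAAL"])
        b = MultipleAlignment(["b1", "b2"], ["MKVLWAAG", "MKVLWAAG"])
        tree = specialized_phylogeny({"A": a, "B": b}, n_replicates=5, seed=0)
        assert sorted(tree.leaf_names()) == ["A", "B"]

    def test_requires_two_clusters_and_nonempty_members(self):
        a = MultipleAlignment(["a1"], ["MKVLW"])
        with pytest.raises(ValueError):
            specialized_phylogeny({"A": a}, n_replicates=1, seed=0)

    def test_seeded_determinism_with_extras(self):
        records, _ = make_partition_benchmark(
            3, members_per_clade=3, length=200, seed=6
        )
        msa = _aligned_msa(records)
        clusters = {
            f"K{c}": msa.subset([f"K{c}_{k}" for k in range(3)]) for c in range(3)
        }
        extra = [SequenceRecord(id="OUT", residues=records[0].residues[:150])]
        t1 = specialized_phylogeny(clusters, extra, n_replicates=10, seed=2)
        t2 = specialized_phylogeny(clusters, extra, n_replicates=10, seed=2)
        assert t1.newick(with_supports=True) == t2.newick(with_supports=True)
        assert "OUT" in t1.leaf_names()
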