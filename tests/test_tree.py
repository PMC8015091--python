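"""UPGMA/NJ correctness on matrices built from known trees, Newick round trips."""

import numpy as np
import pytest

from wgks import (
    CorrelationMatrix,
    InvalidInputError,
    TreeNode,
    neighbor_joining,
    read_newick,
    upgma,
    write_newick,
)

from conftest import random_tree


def matrix_from_distances(labels, dist):
    """Similarity matrix whose 1-s transform equals the given distances."""
    n = len(labels)
    M = np.ones((n, n))
    for (a, b), d in dist.items():
        i, j = labels.index(a), labels.index(b)
        M[i, j] = M[j, i] = 1.0 - d
    return CorrelationMatrix(tuple(labels), M)


def tree_distance_matrix(tree):
    pairs = tree.leaf_distances()
    labels = sorted(tree.leaf_labels())
    return matrix_from_distances(labels, pairs)


class TestUpgma:
    def test_two_leaf_cherry(self):
        m = matrix_from_distances(["A", "B"], {("A", "B"): 0.1})
        t = upgma(m)
        assert sorted(t.leaf_labels()) == ["A", "B"]
        assert all(abs(l - 0.05) < 1e-12 for _, l in t.children)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_ultrametric_tree_exactly(self, seed):
        # build an ultrametric tree, take its distances, invert
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        # random ultrametric: agglomerate leaves at increasing heights
        nodes = [(TreeNode(label=f"t{i}"), 0.0) for i in range(n)]
        h = 0.0
        while len(nodes) > 1:
            h += float(rng.uniform(0.01, 0.1))
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            (b, hb) = nodes.pop(j)
            (a, ha) = nodes.pop(i)
            nodes.append((TreeNode(children=[(a, h - ha), (b, h - hb)]), h))
        truth = nodes[0][0]
        m = tree_distance_matrix(truth)
        got = upgma(m)
        assert got.equals(truth, tol=1e-9)

    def test_ultrametric_output_on_noisy_input(self):
        rng = np.random.default_rng(3)
        n = 7
        eps = rng.uniform(0.2, 0.8, size=(n, n))
        D = (eps + eps.T) / 2.0
        np.fill_diagonal(D, 0.0)
        m = CorrelationMatrix(tuple(f"s{i}" for i in range(n)), 1.0 - D)
        depths = upgma(m).depths()
        assert max(depths.values()) - min(depths.values()) <= 1e-9

    def test_label_permutation_only_permutes_leaves(self):
        rng = np.random.default_rng(9)
        truth = random_tree(rng, 6, min_bl=0.02, max_bl=0.15)
        m = tree_distance_matrix(truth)
        perm = list(np.random.default_rng(1).permutation(m.n))
        m2 = CorrelationMatrix(
            tuple(m.labels[i] for i in perm), m.values[np.ix_(perm, perm)]
        )
        assert upgma(m).equals(upgma(m2), tol=1e-9)

    def test_agrees_with_scipy_cophenet(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(12)
        eps = rng.uniform(0.1, 0.9, size=(6, 6))
        D = (eps + eps.T) / 2.0
        np.fill_diagonal(D, 0.0)
        m = CorrelationMatrix(tuple(f"s{i}" for i in range(6)), 1.0 - D)
        t = upgma(m)
        got = t.leaf_distances()
        Z = linkage(squareform(m.distances(), checks=False), method="average")
        coph = squareform(cophenet(Z))
        for i in range(6):
            for j in range(i + 1, 6):
                key = tuple(sorted((f"s{i}", f"s{j}")))
                assert got[key] == pytest.approx(coph[i, j], abs=1e-9)


class TestNeighborJoining:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_additive_tree(self, seed):
        rng = np.random.default_rng(100 + seed)
        truth = random_tree(rng, int(rng.integers(4, 8)), min_bl=0.02, max_bl=0.2)
        m = tree_distance_matrix(truth)
        got = neighbor_joining(m)
        # additive matrices are recovered exactly: compare path lengths
        want = truth.leaf_distances()
        have = got.leaf_distances()
        for key, d in want.items():
            assert have[key] == pytest.approx(d, abs=1e-9)

    def test_agrees_with_skbio(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(7)
        truth = random_tree(rng, 6, min_bl=0.02, max_bl=0.2)
        m = tree_distance_matrix(truth)
        ours = neighbor_joining(m)
        ref = nj(DistanceMatrix(m.distances(), ids=list(m.labels)))
        ref_d = {
            tuple(sorted((a.name, b.name))): ref.find(a.name).distance(ref.find(b.name))
            for i, a in enumerate(ref.tips())
            for b in list(ref.tips())[i + 1:]
        }
        have = ours.leaf_distances()
        for key, d in ref_d.items():
            assert have[key] == pytest.approx(d, abs=1e-9)

    def test_star_matrix_gives_zero_internal_branches(self):
        labels = ["a", "b", "c", "d"]
        M = np.full((4, 4), 0.5)
        np.fill_diagonal(M, 1.0)
        t = neighbor_joining(CorrelationMatrix(tuple(labels), M))
        # every leaf at equal depth, internal branches ~0
        dists = t.leaf_distances()
        assert all(abs(d - 0.5) < 1e-9 for d in dists.values())

    def test_ultrametric_input_matches_upgma_topology(self):
        rng = np.random.default_rng(21)
        nodes = [(TreeNode(label=f"t{i}"), 0.0) for i in range(6)]
        h = 0.0
        while len(nodes) > 1:
            h += float(rng.uniform(0.02, 0.1))
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            (b, hb) = nodes.pop(j)
            (a, ha) = nodes.pop(i)
            nodes.append((TreeNode(children=[(a, h - ha), (b, h - hb)]), h))
        m = tree_distance_matrix(nodes[0][0])
        want = upgma(m).leaf_distances()
        have = neighbor_joining(m).leaf_distances()
        for key, d in want.items():
            assert have[key] == pytest.approx(d, abs=1e-9)

    def test_too_few_leaves_rejected(self):
        m = matrix_from_distances(["A", "B"], {("A", "B"): 0.1})
        with pytest.raises(InvalidInputError):
            neighbor_joining(m)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(5)
        eps = rng.uniform(0.1, 0.9, size=(7, 7))
        D = (eps + eps.T) / 2.0  # generically non-additive
        np.fill_diagonal(D, 0.0)
        m = CorrelationMatrix(tuple(f"s{i}" for i in range(7)), 1.0 - D)
        t = neighbor_joining(m)

        def walk(node):
            for child, length in node.children:
                assert length >= 0.0
                walk(child)

        walk(t)


class TestNewick:
    def test_cherry_serialization(self):
        t = TreeNode(children=[(TreeNode(label="A"), 0.05), (TreeNode(label="B"), 0.05)])
        assert write_newick(t, precision=2) == "(A:0.05,B:0.05);"

    @pytest.mark.parametrize("seed", range(50))
    def test_roundtrip_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, int(rng.integers(2, 12)))
        back = read_newick(write_newick(t, precision=9))
        assert back.equals(t, tol=1e-6)

    def test_labels_with_spaces_survive(self):
        t = TreeNode(children=[
            (TreeNode(label="Ailurus fulgens"), 0.1),
            (TreeNode(label="Mustela (sp.)"), 0.2),
        ])
        text = write_newick(t)
        assert "'Ailurus fulgens'" in text
        back = read_newick(text)
        assert sorted(back.leaf_labels()) == ["Ailurus fulgens", "Mustela (sp.)"]

    def test_duplicate_leaves_rejected(self):
        t = TreeNode(children=[(TreeNode(label="A"), 0.1), (TreeNode(label="A"), 0.2)])
        with pytest.raises(InvalidInputError):
            write_newick(t)
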