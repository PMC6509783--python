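"""Monophyly, origin counting, sister composition, neighbor joining."""

import itertools

import dendropy
import numpy as np
import pytest

from gh45tools.treescan import (TreeError, clade_report, count_origins,
                                is_monophyletic, nj_tree, read_newick,
                                root_on_outgroup, sister_composition,
                                support_scale)


def _bipartitions(tree):
    """Non-trivial leaf bipartitions of an unrooted tree, as frozensets."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            out.add(frozenset({below, leaves - below}))
    return out


class TestNewick:
    def test_support_scale_detection(self):
        pp = read_newick("((A:1,B:1)0.95:1,(C:1,D:1)0.7:1);")
        bs = read_newick("((A:1,B:1)85:1,(C:1,D:1)44:1);")
        plain = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert support_scale(pp) == "pp"
        assert support_scale(bs) == "bootstrap"
        assert support_scale(plain) is None

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            read_newick("((A,B),(A,C));")


class TestMonophyly:
    def test_single_leaf_is_trivially_monophyletic(self):
        tree = read_newick("((A,B),(C,D));")
        assert is_monophyletic(tree, {"A"}) == (True, None)

    def test_four_taxon_cases(self):
        tree = read_newick("((A,B)90,(C,D)80);")
        ok, support = is_monophyletic(tree, {"A", "B"})
        assert ok and support == 90
        assert is_monophyletic(tree, {"A", "C"})[0] is False

    def test_complement_is_monophyletic_unrooted(self):
        tree = read_newick("((A,B),(C,D));")
        for group in ({"A", "B"}, {"C", "D"}, {"A", "B", "C"}):
            comp = {"A", "B", "C", "D"} - group
            assert is_monophyletic(tree, group)[0] == \
                is_monophyletic(tree, comp)[0]

    def test_rooted_mode_rejects_complement(self):
        tree = read_newick("((A,B),(C,D));")
        assert is_monophyletic(tree, {"A", "B"}, rooted=True)[0] is True
        # {B,C,D} is a bipartition side but not a rooted clade
        assert is_monophyletic(tree, {"B", "C", "D"}, rooted=True)[0] is False
        assert is_monophyletic(tree, {"B", "C", "D"}, rooted=False)[0] is True

    def test_unknown_leaf_rejected(self):
        tree = read_newick("((A,B),(C,D));")
        with pytest.raises(TreeError, match="unknown"):
            is_monophyletic(tree, {"A", "Z"})

    def test_complement_equivalence_on_random_trees(self):
        rng = np.random.default_rng(2)
        taxa = [f"t{i}" for i in range(8)]
        for rep in range(10):
            tree = _random_tree(rng, taxa)
            k = int(rng.integers(2, 7))
            group = set(rng.choice(taxa, size=k, replace=False))
            comp = set(taxa) - group
            assert is_monophyletic(tree, group)[0] == \
                is_monophyletic(tree, comp)[0]


class TestOrigins:
    def test_monophyletic_group_has_one_origin(self):
        tree = read_newick("(O,((A1,A2),(B1,B2)));")
        n, subtrees = count_origins(tree, {"A1", "A2"}, {"O"})
        assert n == 1 and subtrees == [frozenset({"A1", "A2"})]

    def test_interleaved_group_has_two_origins(self):
        tree = read_newick("(O,((A1,X),(A2,Y)));")
        n, subtrees = count_origins(tree, {"A1", "A2"}, {"O"})
        assert n == 2
        assert sorted(sorted(s) for s in subtrees) == [["A1"], ["A2"]]

    def test_origin_count_bounded_by_group_size(self):
        tree = read_newick("(O,(((A1,F1),(A2,F2)),((A3,F3),G)));")
        n, _ = count_origins(tree, {"A1", "A2", "A3"}, {"O"})
        assert n == 3

    def test_group_overlapping_outgroup_rejected(self):
        tree = read_newick("(O,(A,B));")
        with pytest.raises(TreeError, match="overlap"):
            count_origins(tree, {"O", "A"}, {"O"})

    def test_origins_one_iff_rooted_monophyly(self):
        rng = np.random.default_rng(9)
        taxa = [f"t{i}" for i in range(7)]
        for rep in range(10):
            tree = _random_tree(rng, taxa + ["OUT"])
            group = set(rng.choice(taxa, size=3, replace=False))
            n, _ = count_origins(tree, group, {"OUT"})
            rooted = root_on_outgroup(tree, {"OUT"})
            mono, _ = is_monophyletic(rooted, group, rooted=True)
            assert (n == 1) == mono
            assert 1 <= n <= len(group)


class TestSisterComposition:
    LIN = {"G1": "beetle", "G2": "beetle", "F1": "fungi", "F2": "fungi",
           "O": "outgroup"}

    def test_simple_sister(self):
        tree = read_newick("(O,((G1,G2),(F1,F2)));")
        comp, _ = sister_composition(tree, {"G1", "G2"}, self.LIN,
                                     outgroup={"O"})
        assert comp == {"fungi": 2}

    def test_sister_of_near_total_group(self):
        tree = read_newick("(O,(F1,(G1,G2)));")
        comp, _ = sister_composition(tree, {"G1", "G2", "F1"}, self.LIN,
                                     outgroup={"O"})
        assert comp == {"outgroup": 1}

    def test_non_monophyletic_group_rejected(self):
        tree = read_newick("(O,((G1,F1),(G2,F2)));")
        with pytest.raises(TreeError, match="not a"):
            sister_composition(tree, {"G1", "G2"}, self.LIN, outgroup={"O"})

    def test_clade_report_composes(self):
        tree = read_newick("(O,((G1,G2)0.99,(F1,F2)0.9)0.8);")
        rep = clade_report(tree, "beetles", {"G1", "G2"},
                           lineage=self.LIN, outgroup={"O"})
        assert rep.is_monophyletic and rep.n_origins == 1
        assert rep.support == 0.99
        assert rep.sister_composition == {"fungi": 2}


def _random_tree(rng, taxa, scale=1.0):
    """Random binary tree by sequential attachment, random branch lengths."""
    newick = _random_topology(rng, list(taxa), scale)
    return read_newick(newick)


def _random_topology(rng, taxa, scale):
    nodes = [f"{t}:{rng.uniform(0.1, 1.0) * scale:.4f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (f"({nodes[i]},{nodes[j]}):"
                  f"{rng.uniform(0.1, 1.0) * scale:.4f}")
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";"


def _tree_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(["a", "b", "c"], d)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        d[3, 2] = d[2, 3] = 7
        d[3, 3] = 0
        tree = nj_tree(list("abcd"), d)
        assert is_monophyletic(tree, {"a", "b"})[0]
        assert is_monophyletic(tree, {"c", "d"})[0]

    def test_equidistant_matrix_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(list("abcd"), d)
        t2 = nj_tree(list("abcd"), d)
        assert _bipartitions(t1) == _bipartitions(t2)

    @pytest.mark.parametrize("bad", [
        np.array([[0, 1], [1, 0]], dtype=float),                # too small
        np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float),     # asymmetric
        np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0]], float),   # negative
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(TreeError):
            nj_tree([f"x{i}" for i in range(len(bad))], bad)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(31)
        for rep in range(15):
            k = int(rng.integers(5, 9))
            true = _random_tree(rng, [f"t{i}" for i in range(k)])
            labels, d = _tree_distances(true)
            est = nj_tree(labels, d)
            assert _bipartitions(est) == _bipartitions(true)

    def test_matches_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        import io

        rng = np.random.default_rng(17)
        for rep in range(5):
            true = _random_tree(rng, [f"t{i}" for i in range(6)])
            labels, d = _tree_distances(true)
            mine = nj_tree(labels, d)
            ref = skbio_nj(DistanceMatrix(d, labels))
            ref_tree = read_newick(str(ref))
            assert _bipartitions(mine) == _bipartitions(ref_tree)
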