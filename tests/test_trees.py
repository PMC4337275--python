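"""Newick ingestion, outgroup rooting, and neighbor joining."""

import random

import numpy as np
import pytest

from portrace.trees import (
    TreeError,
    leaf_distances,
    nj_build,
    parse_newick,
    root_on_outgroup,
    splits,
    write_newick,
)


# -- independent random-tree oracle for NJ tests ----------------------------

def random_tuple_tree(n_leaves: int, rng: random.Random):
    """A random binary tree as nested tuples; leaves are (name, length)."""
    nodes = [(f"L{i}", round(rng.uniform(0.1, 1.0), 4)) for i in range(n_leaves)]
    while len(nodes) > 3:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(((a, b), round(rng.uniform(0.1, 1.0), 4)))
    return tuple(nodes)  # unrooted: three subtrees at the basal node


def tuple_tree_leaves(node):
    payload = node[0]
    if isinstance(payload, str):
        return [payload]
    return [x for child in payload for x in tuple_tree_leaves(child)]


def tuple_tree_distances(star):
    """Path-length matrix computed by graph traversal on the tuples."""
    import itertools

    labels = [x for subtree in star for x in tuple_tree_leaves(subtree)]

    graph = {}
    counter = itertools.count()

    def build(node, parent):
        payload, length = node
        me = payload if isinstance(payload, str) else f"__n{next(counter)}"
        graph.setdefault(me, []).append((parent, length))
        graph.setdefault(parent, []).append((me, length))
        if not isinstance(payload, str):
            for child in payload:
                build(child, me)

    for subtree in star:
        build(subtree, "__root")

    n = len(labels)
    dist = np.zeros((n, n))
    for i, src in enumerate(labels):
        # Dijkstra-free BFS: trees have unique paths
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in graph[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        for j, dst in enumerate(labels):
            dist[i, j] = seen[dst]
    return labels, dist


def tuple_tree_splits(star):
    all_leaves = frozenset(x for s in star for x in tuple_tree_leaves(s))
    out = set()

    def walk(node):
        payload, _ = node
        if isinstance(payload, str):
            return frozenset([payload])
        below = frozenset()
        for child in payload:
            below |= walk(child)
        other = all_leaves - below
        canon = min(below, other, key=lambda s: (len(s), sorted(s)))
        if len(canon) >= 2:
            out.add(canon)
        return below

    for subtree in star:
        walk(subtree)
    return out


# -- newick -----------------------------------------------------------------

class TestNewick:
    def test_parse_supports_and_lengths(self):
        tree = parse_newick("((A:1,B:1)0.99:1,C:2);")
        internal = [c for c in tree.root.children if not c.is_leaf][0]
        assert internal.support == pytest.approx(0.99)
        assert internal.length == pytest.approx(1.0)
        assert set(tree.leaf_names()) == {"A", "B", "C"}

    def test_bootstrap_percentages_normalized(self):
        tree = parse_newick("((A:1,B:1)88:1,C:2);")
        internal = [c for c in tree.root.children if not c.is_leaf][0]
        assert internal.support == pytest.approx(0.88)

    def test_round_trip_of_simulated_tree(self):
        from portrace.simulate import simulate_gene_tree

        tree, _ = simulate_gene_tree(n_duplications=1, n_hgt=1, seed=4)
        text = write_newick(tree)
        again = parse_newick(text, tree.meta)
        assert write_newick(again) == text
        assert sorted(again.leaf_names()) == sorted(tree.leaf_names())

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A:1,B:1;")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")


class TestRooting:
    def test_quartet_roots_on_pendant_edge(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,O:4);")
        rooted = root_on_outgroup(tree, {"O"})
        assert rooted.rooted
        sides = [set(c.leaf_names()) for c in rooted.root.children]
        assert sides[0] == {"O"}
        assert sides[1] == {"A", "B", "C"}

    def test_split_edge_length_apportioned_half_half(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):2);")
        rooted = root_on_outgroup(tree, {"C", "D"})
        lengths = [c.length for c in rooted.root.children]
        assert lengths == [pytest.approx(1.5), pytest.approx(1.5)]

    def test_outgroup_of_simulated_tree_separates_ingroup(self):
        from portrace.simulate import simulate_gene_tree

        tree, _ = simulate_gene_tree(seed=2)
        cyano = [
            n for n in tree.leaf_names()
            if tree.lineage_of(n) == "cyanobacteria"
        ]
        rooted = root_on_outgroup(tree, cyano)
        sides = [set(c.leaf_names()) for c in rooted.root.children]
        assert sides[0] == set(cyano)
        assert sides[1] == set(tree.leaf_names()) - set(cyano)

    def test_patristic_distances_preserved_by_rerooting(self):
        tree = parse_newick("(((A:1,B:2):0.5,C:1):1,(D:2,E:1):0.7);")
        labels, before = leaf_distances(tree)
        rooted = root_on_outgroup(tree, {"D", "E"})
        labels2, after = leaf_distances(rooted)
        idx = [labels2.index(x) for x in labels]
        assert np.allclose(after[np.ix_(idx, idx)], before, atol=1e-9)

    def test_non_monophyletic_outgroup_lists_intruders(self):
        tree = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.raises(TreeError, match="intruding"):
            root_on_outgroup(tree, {"A", "B"})


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_build(d, ["A", "B", "C"])
        by_name = {c.name: c.length for c in tree.root.children}
        assert by_name["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert by_name["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert by_name["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        rng = random.Random(0)
        star = random_tuple_tree(5, rng)
        labels, d = tuple_tree_distances(star)
        tree = nj_build(d, labels)
        assert splits(tree) == tuple_tree_splits(star)
        labels2, d2 = leaf_distances(tree)
        idx = [labels2.index(x) for x in labels]
        assert np.allclose(d2[np.ix_(idx, idx)], d, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_up_to_eight_taxa(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 8)
        star = random_tuple_tree(n, rng)
        labels, d = tuple_tree_distances(star)
        tree = nj_build(d, labels)
        assert splits(tree) == tuple_tree_splits(star)
        labels2, d2 = leaf_distances(tree)
        idx = [labels2.index(x) for x in labels]
        assert np.allclose(d2[np.ix_(idx, idx)], d, atol=1e-8)

    def test_random_metric_gives_valid_tree(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = nj_build(d, [f"t{i}" for i in range(6)])
        assert sorted(tree.leaf_names()) == [f"t{i}" for i in range(6)]
        for node in tree.root.preorder():
            if node is not tree.root:
                assert node.length >= -1e-9

    def test_invalid_input_rejected(self):
        bad = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(Exception):
            nj_build(bad, ["A", "B"])
        with pytest.raises(Exception):
            nj_build(np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0.0]]),
                     ["A", "B", "C"])
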