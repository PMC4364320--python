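"""Distance matrices, neighbor joining and clade checks.

Oracles: random additive matrices from random trees (NJ must return the
generating tree exactly), exhaustive topology enumeration with
least-squares branch fitting for n <= 6, and scikit-bio's independent NJ
implementation.
"""

import io
import itertools
import random

import numpy as np
import pytest

import networkx as nx
import skbio

from lmwgs import reference
from lmwgs.errors import InputError, ValidationError
from lmwgs.phylo import (
    DistanceMatrix,
    TreeNode,
    check_monophyly,
    neighbor_joining,
    pdistance_matrix,
)

# --------------------------------------------------------------------------
# oracle helpers: edge-list trees


def random_tree(taxa, rng):
    """Random unrooted binary tree as {edge: length}."""
    taxa = list(taxa)
    edges = {}
    internal = [f"_{i}" for i in range(len(taxa))]
    # start from a 3-leaf star
    center = internal.pop()
    for leaf in taxa[:3]:
        edges[frozenset((center, leaf))] = rng.uniform(0.1, 1.0)
    for leaf in taxa[3:]:
        edge = rng.choice(sorted(edges, key=sorted))
        u, v = sorted(edge)
        length = edges.pop(edge)
        w = internal.pop()
        edges[frozenset((u, w))] = length / 2
        edges[frozenset((w, v))] = length / 2
        edges[frozenset((w, leaf))] = rng.uniform(0.1, 1.0)
    return edges


def tree_graph(edges):
    g = nx.Graph()
    for edge, length in edges.items():
        u, v = edge
        g.add_edge(u, v, weight=length)
    return g


def distances_from_tree(edges, taxa):
    g = tree_graph(edges)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nx.shortest_path_length(
            g, taxa[i], taxa[j], weight="weight"
        )
    return DistanceMatrix(taxa=tuple(taxa), values=d)


def edge_split_map(edges, taxa):
    """Canonical bipartition side -> branch length for every edge."""
    g = tree_graph(edges)
    full = frozenset(taxa)
    out = {}
    for edge, length in edges.items():
        u, v = edge
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(nx.node_connected_component(h, u)) & full
        side = min(side, full - side, key=lambda s: (len(s), sorted(s)))
        out[side] = length
    return out


def node_split_map(tree: TreeNode):
    full = frozenset(tree.leaves())
    out = {}

    def walk(node):
        for child, length in node.children:
            side = frozenset(child.leaves())
            key = min(side, full - side, key=lambda s: (len(s), sorted(s)))
            out[key] = out.get(key, 0.0) + length
            walk(child)

    walk(tree)
    return out


def enumerate_topologies(taxa):
    """All unrooted binary topologies over ``taxa`` as edge sets."""
    taxa = list(taxa)
    first = [{frozenset(("_0", t)) for t in taxa[:3]}]
    trees = first
    counter = [1]
    for k, leaf in enumerate(taxa[3:], start=0):
        new_trees = []
        for edges in trees:
            for edge in edges:
                u, v = sorted(edge)
                w = f"_n{k}_{u}_{v}"
                rest = set(edges) - {edge}
                rest |= {
                    frozenset((u, w)),
                    frozenset((w, v)),
                    frozenset((w, leaf)),
                }
                new_trees.append(rest)
        trees = new_trees
    return trees


def least_squares_sse(edge_set, dm: DistanceMatrix):
    edges = sorted(edge_set, key=sorted)
    g = nx.Graph(list(e) for e in edges)
    pairs = list(itertools.combinations(range(len(dm.taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    index = {e: k for k, e in enumerate(edges)}
    for row, (i, j) in enumerate(pairs):
        path = nx.shortest_path(g, dm.taxa[i], dm.taxa[j])
        for u, v in zip(path, path[1:]):
            A[row, index[frozenset((u, v))]] = 1.0
        y[row] = dm.values[i, j]
    _, residual, *_ = np.linalg.lstsq(A, y, rcond=None)
    if residual.size:
        return float(residual[0])
    fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(((fit - y) ** 2).sum())


def topology_splits(edge_set, taxa):
    lengths = {e: 1.0 for e in edge_set}
    return set(edge_split_map(lengths, taxa))


# --------------------------------------------------------------------------
# p-distances


class TestPDistance:
    def test_identical_pair_distance_zero(self):
        seqs = {
            "a": "ACGTACGTAC" * 10,
            "b": "ACGTACGTAC" * 10,
            "c": "ACGTTCGTAC" * 10,
        }
        dm = pdistance_matrix(seqs)
        assert dm.values[dm.taxa.index("a"), dm.taxa.index("b")] == 0.0

    def test_three_mismatches_in_300_columns(self):
        rng = random.Random(1)
        a = "".join(rng.choice("ACGT") for _ in range(300))
        b = list(a)
        for pos, base in [(10, None), (150, None), (290, None)]:
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        c = a[:100] + a[101:]  # third taxon, one deletion
        dm = pdistance_matrix({"a": a, "b": b, "c": c})
        assert dm.values[0, 1] == pytest.approx(3 / 300, abs=1e-12)

    def test_bounds_and_symmetry(self):
        seqs = {k: reference.variant_sequences()[k]
                for k in ("TuA3-385a", "TuA3-502a", "TuA3-460")}
        dm = pdistance_matrix(seqs)
        assert np.all(dm.values >= 0) and np.all(dm.values <= 1)
        assert np.allclose(dm.values, dm.values.T)

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(InputError):
            pdistance_matrix({"a": "ACGT", "b": "ACGT"})

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValidationError):
            DistanceMatrix(taxa=("a", "b", "c"), values=values)


# --------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_four_taxon_additive_case_by_hand(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives these six distances
        taxa = ("A", "B", "C", "D")
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        values = np.zeros((4, 4))
        for (u, v), x in d.items():
            i, j = taxa.index(u), taxa.index(v)
            values[i, j] = values[j, i] = x
        tree = neighbor_joining(DistanceMatrix(taxa=taxa, values=values))
        splits = node_split_map(tree)
        assert splits[frozenset({"A"})] == pytest.approx(1.0)
        assert splits[frozenset({"B"})] == pytest.approx(2.0)
        assert splits[frozenset({"C"})] == pytest.approx(3.0)
        assert splits[frozenset({"D"})] == pytest.approx(4.0)
        assert splits[frozenset({"A", "B"})] == pytest.approx(1.0)

    def test_three_taxa_star_formulas(self):
        values = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa=("a", "b", "c"), values=values))
        splits = node_split_map(tree)
        assert splits[frozenset({"a"})] == pytest.approx(1.0)
        assert splits[frozenset({"b"})] == pytest.approx(2.0)
        assert splits[frozenset({"c"})] == pytest.approx(3.0)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_recovers_random_additive_trees_exactly(self, n):
        rng = random.Random(100 + n)
        taxa = [f"t{i}" for i in range(n)]
        for _ in range(5):
            edges = random_tree(taxa, rng)
            dm = distances_from_tree(edges, taxa)
            tree = neighbor_joining(dm)
            want = edge_split_map(edges, taxa)
            got = node_split_map(tree)
            assert set(got) == set(want)
            for side, length in want.items():
                assert got[side] == pytest.approx(length, abs=1e-9)

    @pytest.mark.parametrize("n", [5, 6])
    def test_agrees_with_exhaustive_least_squares_search(self, n):
        rng = random.Random(7 * n)
        taxa = [f"t{i}" for i in range(n)]
        for _ in range(3):
            edges = random_tree(taxa, rng)
            dm = distances_from_tree(edges, taxa)
            scored = [
                (least_squares_sse(topo, dm), k)
                for k, topo in enumerate(enumerate_topologies(taxa))
            ]
            best_sse, best_k = min(scored)
            assert best_sse == pytest.approx(0.0, abs=1e-12)
            best_topo = enumerate_topologies(taxa)[best_k]
            nj_splits = set(node_split_map(neighbor_joining(dm)))
            want = topology_splits(best_topo, taxa)
            assert {s for s in nj_splits if len(s) > 1} == {
                s for s in want if len(s) > 1
            }

    def test_matches_scikit_bio_on_noisy_matrices(self):
        rng = random.Random(55)
        np_rng = np.random.default_rng(55)
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(3):
            edges = random_tree(taxa, rng)
            dm = distances_from_tree(edges, taxa)
            noise = np_rng.uniform(0.0, 0.02, dm.values.shape)
            noisy = dm.values + (noise + noise.T)  # exactly symmetric
            np.fill_diagonal(noisy, 0.0)
            ours = neighbor_joining(DistanceMatrix(tuple(taxa), noisy))
            theirs = skbio.tree.nj(
                skbio.DistanceMatrix(noisy, ids=taxa)
            )
            ours_sk = skbio.TreeNode.read(io.StringIO(ours.newick()))
            rfd = ours_sk.compare_rfd(theirs)
            assert rfd == 0.0

    def test_leaf_set_preserved_and_length_stable_under_relabeling(self):
        rng = random.Random(2)
        taxa = [f"x{i}" for i in range(6)]
        edges = random_tree(taxa, rng)
        dm = distances_from_tree(edges, taxa)
        tree = neighbor_joining(dm)
        assert sorted(tree.leaves()) == sorted(taxa)
        perm = list(reversed(range(len(taxa))))
        taxa2 = [taxa[i] for i in perm]
        values2 = dm.values[np.ix_(perm, perm)]
        tree2 = neighbor_joining(DistanceMatrix(tuple(taxa2), values2))
        assert tree.total_length() == pytest.approx(tree2.total_length())


class TestMonophyly:
    def test_gene_variants_form_clades_in_reference_tree(self, pipeline_run):
        _, report = pipeline_run
        assert all(report["gene_monophyly"].values())

    def test_itype_clade_separates_from_m_and_s(self, pipeline_run):
        _, report = pipeline_run
        assert report["type_monophyly"]["i"] is True

    def test_singleton_label_is_trivially_monophyletic(self):
        values = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), values))
        result = check_monophyly(tree, {"a": "x", "b": "y", "c": "y"})
        assert result["x"] is True

    def test_label_spanning_tree_is_not_monophyletic(self):
        rng = random.Random(4)
        taxa = [f"t{i}" for i in range(6)]
        dm = distances_from_tree(random_tree(taxa, rng), taxa)
        tree = neighbor_joining(dm)
        # alternate labels so neither class can be separated by one edge
        labels = {t: ("p" if i % 2 else "q") for i, t in enumerate(taxa)}
        result = check_monophyly(tree, labels)
        assert not (result["p"] and result["q"])

    def test_unlabeled_leaf_is_an_error(self):
        values = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), values))
        with pytest.raises(InputError, match="c"):
            check_monophyly(tree, {"a": "x", "b": "y"})
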