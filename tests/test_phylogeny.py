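"""Neighbor joining: closed-form cases, additive recovery, round-trips."""

import itertools

import dendropy
import numpy as np
import pytest

from solomine.errors import DegenerateInputError
from solomine.phylogeny import (DistanceMatrix, TreeNode, distance_matrix,
                                neighbor_joining, write_annotated_newick)


def _dm(ids, d):
    return DistanceMatrix(ids=tuple(ids), d=np.array(d, dtype=float))


def test_distance_matrix_from_sequences():
    dm = distance_matrix({"a": "MKLV", "b": "MKIV", "c": "MKLV"})
    i, j = dm.ids.index("a"), dm.ids.index("b")
    assert dm.d[i, j] == pytest.approx(0.25)
    assert dm.d[dm.ids.index("a"), dm.ids.index("c")] == 0.0
    assert np.allclose(dm.d, dm.d.T)


def test_distance_matrix_needs_two():
    with pytest.raises(DegenerateInputError):
        distance_matrix({"a": "MKLV"})


def test_three_taxon_closed_form():
    tree = neighbor_joining(_dm("ABC", [[0, .2, .3], [.2, 0, .4], [.3, .4, 0]]))
    lengths = {c.name: ln for c, ln in tree.children}
    assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})


def test_nj_needs_three_taxa():
    with pytest.raises(DegenerateInputError):
        neighbor_joining(_dm("AB", [[0, .1], [.1, 0]]))


def _random_additive(rng, n):
    """A random binary tree over n leaves; returns (leaf ids, distances)."""
    nodes = [TreeNode(name=f"L{i:02d}") for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[(nodes[i], rng.uniform(0.1, 1.0)),
                                    (nodes[j], rng.uniform(0.1, 1.0))])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=[(nodes[0], rng.uniform(0.1, 1.0)),
                              (nodes[1], rng.uniform(0.1, 1.0))])
    paths = root.path_lengths()
    ids = sorted(root.leaf_names())
    d = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        d[a, b] = d[b, a] = paths[(ids[a], ids[b])]
    return ids, d


def test_recovers_additive_trees_exactly(rng):
    for n in (4, 6, 9, 12):
        for _ in range(5):
            ids, d = _random_additive(rng, n)
            tree = neighbor_joining(_dm(ids, d))
            paths = tree.path_lengths()
            for a, b in itertools.combinations(range(n), 2):
                assert paths[(ids[a], ids[b])] == pytest.approx(
                    d[a, b], abs=1e-9)


def _splits(tree: TreeNode) -> set[frozenset[str]]:
    all_leaves = frozenset(tree.leaf_names())
    out = set()

    def walk(node):
        for child, _ in node.children:
            side = frozenset(child.leaf_names())
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(min(side, all_leaves - side, key=sorted))
            walk(child)

    walk(tree)
    return out


def _enumerate_topologies(leaves):
    """All unrooted binary topologies as edge lists over named nodes."""
    first = [("I0", leaves[0]), ("I0", leaves[1]), ("I0", leaves[2])]
    trees = [first]
    for k, leaf in enumerate(leaves[3:], start=1):
        new = []
        for edges in trees:
            for idx in range(len(edges)):
                u, v = edges[idx]
                w = f"I{k}"
                grown = edges[:idx] + edges[idx + 1:]
                grown = grown + [(u, w), (w, v), (w, leaf)]
                new.append(grown)
        trees = new
    return trees


def _topology_splits(edges, leaves):
    import networkx as nx

    g = nx.Graph(edges)
    out = set()
    leafset = frozenset(leaves)
    for u, v in edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u)
                         if x in leafset)
        if 1 < len(side) < len(leaves) - 1:
            out.add(min(side, leafset - side, key=sorted))
    return out


def _fits_additively(edges, leaves, dm):
    """Least-squares branch lengths; True if the matrix fits exactly."""
    import networkx as nx

    g = nx.Graph()
    for idx, (u, v) in enumerate(edges):
        g.add_edge(u, v, idx=idx)
    pairs = list(itertools.combinations(leaves, 2))
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    for r, (x, y) in enumerate(pairs):
        path = nx.shortest_path(g, x, y)
        for u, v in zip(path, path[1:]):
            A[r, g[u][v]["idx"]] = 1
        b[r] = dm[leaves.index(x), leaves.index(y)]
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.allclose(A @ sol, b, atol=1e-8) and np.all(sol > -1e-8)


def test_topology_matches_enumeration_oracle(rng):
    # the unique additive topology, found by exhaustive search, equals NJ's
    for n in (5, 6):
        ids, d = _random_additive(rng, n)
        nj_splits = _splits(neighbor_joining(_dm(ids, d)))
        matching = [t for t in _enumerate_topologies(ids)
                    if _fits_additively(t, ids, d)]
        assert len(matching) == 1
        assert _topology_splits(matching[0], ids) == nj_splits


def test_agrees_with_skbio_on_additive_matrix(rng):
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    ids, d = _random_additive(rng, 10)
    ours = _splits(neighbor_joining(_dm(ids, d)))
    sk_tree = skbio_nj(SkbioDM(d, ids))
    sk_newick = sk_tree.__str__()
    dt = dendropy.Tree.get(data=sk_newick, schema="newick")
    theirs = set()
    all_leaves = frozenset(ids)
    for edge in dt.preorder_edge_iter():
        if edge.head_node and not edge.head_node.is_leaf():
            side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
            if 1 < len(side) < len(ids) - 1:
                theirs.add(min(side, all_leaves - side, key=sorted))
    assert ours == theirs


def test_equal_distances_deterministic():
    d = np.full((4, 4), 0.5)
    np.fill_diagonal(d, 0.0)
    t1 = neighbor_joining(_dm("ABCD", d))
    t2 = neighbor_joining(_dm("ABCD", d))
    assert t1.newick() == t2.newick()


def test_newick_roundtrip_preserves_lengths(rng):
    ids, d = _random_additive(rng, 8)
    tree = neighbor_joining(_dm(ids, d))
    nwk, _ = write_annotated_newick(tree)
    dt = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in dt.taxon_namespace}
    ours = tree.path_lengths()
    for a, b in itertools.combinations(ids, 2):
        assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
            ours[(a, b)], abs=1e-9)


def test_annotated_newick_labels_and_sidecar():
    tree = neighbor_joining(_dm("ABC", [[0, .2, .3], [.2, 0, .4], [.3, .4, 0]]))
    nwk, sidecar = write_annotated_newick(
        tree, {"A": {"subgroup_id": 2, "class_hint": "AHL_type",
                     "environment_label": "plant"},
               "ZZZ": {"subgroup_id": 0}})  # unknown leaf: warned, ignored
    assert "A|sg=2|class=AHL_type|env=plant" in nwk
    assert nwk.endswith(";")
    assert list(sidecar.leaf) == ["A", "B", "C"]
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(parsed.leaf_nodes()) == 3
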