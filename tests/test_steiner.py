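"""Steiner-tree heuristic: examples, tree validity, determinism, oracles."""

import networkx as nx
import numpy as np
import pytest

from netpathad.datatypes import GeneSet, Interactome
from netpathad.steiner import (
    NoSeedsError,
    classify_nodes,
    densify,
    steiner_tree,
)
from netpathad.synth import make_interactome

from _oracles import connected_subsets, optimal_steiner_size


def seeds(*names):
    return GeneSet("seeds", names)


def tree_is_valid(result):
    nodes = result.nodes
    if len(nodes) <= 1:
        return len(result.edges) == 0
    if len(result.edges) != len(nodes) - 1:
        return False
    g = nx.Graph(list(result.edges))
    return set(g.nodes) == set(nodes) and nx.is_connected(g)


class TestExamples:
    def test_single_seed(self):
        g = Interactome(edges=[("A", "B")])
        r = steiner_tree(g, seeds("A"))
        assert r.nodes == {"A"} and r.n_edges == 0
        assert len(r.linker_nodes) == 0

    def test_adjacent_seed_pair(self):
        g = Interactome(edges=[("A", "B"), ("B", "C")])
        r = steiner_tree(g, seeds("A", "B"))
        assert r.nodes == {"A", "B"} and r.n_edges == 1

    def test_star_hub_becomes_linker(self):
        g = Interactome(edges=[("H", x) for x in "ACEXY"])
        r = steiner_tree(g, seeds("A", "C", "E"))
        assert r.nodes == {"A", "C", "E", "H"}
        assert r.n_edges == 3
        assert r.linker_nodes.genes == {"H"}

    def test_no_seed_in_graph(self):
        g = Interactome(edges=[("A", "B")])
        with pytest.raises(NoSeedsError):
            steiner_tree(g, seeds("Z"))

    def test_absent_and_isolated_seeds_excluded(self):
        # Q is in a component of its own; Z is absent entirely
        g = Interactome(edges=[("A", "B"), ("B", "C"), ("Q", "Q2")])
        r = steiner_tree(g, seeds("A", "C", "Q", "Z"))
        assert r.seed_nodes.genes == {"A", "C"}
        assert r.excluded_seeds.genes == {"Q", "Z"}

    def test_planted_path_is_unique_connection(self):
        net = make_interactome(10, 0,
                               planted_paths=[("G000001", "G000002", 3)],
                               seed=1)
        r = steiner_tree(net, seeds("G000001", "G000002"))
        assert r.nodes == {"G000001", "G000002", "L0001", "L0002"}
        assert tree_is_valid(r)


class TestDensify:
    def test_triangle_restores_cycle(self):
        g = Interactome(edges=[("A", "B"), ("B", "C"), ("A", "C")])
        t = steiner_tree(g, seeds("A", "B", "C"))
        assert t.n_edges == 2
        d = densify(g, t)
        assert d.n_edges == 3 and d.nodes == t.nodes

    def test_idempotent_and_monotone(self):
        net = make_interactome(60, 200, seed=3)
        seed_set = GeneSet("s", sorted(net.nodes)[:6])
        t = steiner_tree(net, seed_set)
        d1 = densify(net, t)
        d2 = densify(net, d1)
        assert d1.edges == d2.edges and d1.nodes == t.nodes
        assert d1.n_edges >= t.n_edges


class TestClassify:
    def test_all_seed_tree_has_no_linkers(self):
        g = Interactome(edges=[("A", "B"), ("B", "C")])
        r = steiner_tree(g, seeds("A", "B", "C"))
        seed_list, linkers = classify_nodes(r, seeds("A", "B", "C"))
        assert linkers == [] and seed_list == ["A", "B", "C"]

    def test_star_linker_classified(self):
        g = Interactome(edges=[("H", x) for x in "ACE"])
        r = steiner_tree(g, seeds("A", "C", "E"))
        seed_list, linkers = classify_nodes(r, seeds("A", "C", "E"))
        assert linkers == ["H"]
        assert r.seed_coverage(seeds("A", "C", "E")) == 1.0


class TestProperties:
    def test_tree_validity_on_random_instances(self):
        rng = np.random.default_rng(90)
        for rep in range(25):
            n = int(rng.integers(20, 120))
            m = int(rng.integers(n, 4 * n))
            net = make_interactome(n, min(m, n * (n - 1) // 2),
                                   seed=1000 + rep)
            k = int(rng.integers(2, 9))
            seed_set = GeneSet(
                "s", rng.choice(sorted(net.nodes), size=k, replace=False))
            r = steiner_tree(net, seed_set)
            assert tree_is_valid(r)
            assert r.seed_nodes.genes <= seed_set.genes
            assert not (r.seed_nodes.genes & r.linker_nodes.genes)

    def test_determinism(self):
        net = make_interactome(80, 240, seed=5)
        seed_set = GeneSet("s", sorted(net.nodes)[::7][:8])
        r1 = steiner_tree(net, seed_set)
        # rebuild the graph with reversed edge insertion order
        net2 = Interactome(edges=sorted(net.edges, reverse=True),
                           nodes=net.nodes)
        r2 = steiner_tree(net2, seed_set)
        assert r1.edges == r2.edges and r1.nodes == r2.nodes

    def test_matches_exhaustive_oracle_small_graphs(self):
        """Spot version of the full atlas sweep (small n, random seeds)."""
        rng = np.random.default_rng(7)
        checked = 0
        for g in nx.graph_atlas_g()[1:209]:  # all graphs on <= 6 nodes
            if g.number_of_nodes() < 2 or not nx.is_connected(g):
                continue
            _check_against_oracle(g, rng)
            checked += 1
        assert checked > 20

    def test_planted_linker_recovery(self):
        """Linker chains planted in sparse noise are recovered >= 90%."""
        found = total = 0
        for rep in range(50):
            pairs = [("G000010", "G000020", 3), ("G000030", "G000040", 3),
                     ("G000050", "G000060", 3), ("G000070", "G000080", 3)]
            net = make_interactome(300, 300, planted_paths=pairs,
                                   seed=3000 + rep)
            seed_set = GeneSet("s", [a for a, _, _ in pairs]
                               + [b for _, b, _ in pairs])
            r = steiner_tree(net, seed_set)
            planted = {f"L{i:04d}" for i in range(1, 9)}
            total += len(planted)
            found += len(planted & r.nodes)
        assert found / total >= 0.90


def _check_against_oracle(g, rng):
    n = g.number_of_nodes()
    mapping = {v: f"{v:02d}" for v in g.nodes}
    net = Interactome(edges=[(mapping[a], mapping[b]) for a, b in g.edges()],
                      nodes=mapping.values())
    conn = connected_subsets(n, list(g.edges()))
    nodes = sorted(g.nodes)
    for k in (2, 3, 4):
        if k > n:
            break
        chosen = rng.choice(nodes, size=k, replace=False)
        seed_mask = 0
        for v in chosen:
            seed_mask |= 1 << int(v)
        opt = optimal_steiner_size(conn, seed_mask)
        r = steiner_tree(net, GeneSet("s", [mapping[int(v)] for v in chosen]))
        assert tree_is_valid(r)
        assert opt <= r.n_nodes <= 2 * opt - 1
        if nx.is_tree(g):
            assert r.n_nodes == opt
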