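"""Disease-subnetwork inference by a greedy Steiner-tree heuristic.

Given an interactome and a set of seed (disease) genes, the heuristic grows
a forest initialized with one singleton tree per seed and repeatedly links
trees through shortest (hop-count) paths until every seed reachable from
the others lies in one tree.  Non-seed nodes added on connecting paths are
the *linker* genes.  This follows the network-parsimony assumption that
disease molecules communicate along short paths in the interactome.

Implementation notes
--------------------
Each round performs one multi-source breadth-first search labelling every
graph node with its nearest tree; all inter-tree connections realizable at
the minimal hop distance of that round are then merged in canonical-path
order under union-find.  This batched variant of closest-pair merging keeps
the work at O(rounds x |E|) — necessary for interactome-scale graphs — and
retains the classic metric-closure bound: the tree spans at most
2·OPT − 1 nodes, and is exactly optimal when the host graph is a tree.

Ties are broken totally and lexicographically: BFS expands nodes in sorted
order, and candidate paths merge in order of their canonical (orientation-
normalized) node sequences, so identical inputs give identical outputs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .datatypes import GeneSet, Interactome, canonical_edge

__all__ = ["SubnetworkResult", "steiner_tree", "densify", "classify_nodes"]


class NoSeedsError(ValueError):
    pass


@dataclass(frozen=True)
class SubnetworkResult:
    """An inferred subnetwork over seed and linker nodes."""

    seed_nodes: GeneSet
    linker_nodes: GeneSet
    edges: frozenset[tuple[str, str]]
    excluded_seeds: GeneSet
    is_tree: bool = True

    @property
    def nodes(self) -> frozenset[str]:
        return self.seed_nodes.genes | self.linker_nodes.genes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def seed_coverage(self, all_seeds: GeneSet) -> float:
        if len(all_seeds) == 0:
            return 0.0
        return len(self.seed_nodes.genes & all_seeds.genes) / len(all_seeds)


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def add(self, x: str) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: str) -> str:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller name becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def steiner_tree(g: Interactome, seeds: GeneSet) -> SubnetworkResult:
    """Connect the seeds through a greedy heuristic Steiner tree.

    Returns the tree spanning the largest seed-containing merged component;
    seeds absent from the graph, or not connectable to that component, are
    reported in ``excluded_seeds``.
    """
    if g.n_nodes == 0:
        raise NoSeedsError("no seeds in network")
    present = sorted(s for s in seeds.genes if s in g)
    if not present:
        raise NoSeedsError("no seeds in network")

    adj = g.adjacency()
    uf = _UnionFind()
    for s in present:
        uf.add(s)
    forest_nodes: set[str] = set(present)
    forest_edges: set[tuple[str, str]] = set()

    while True:
        labels, dist, parent = _multi_source_bfs(adj, forest_nodes, uf)
        candidates = _meeting_candidates(g, labels, dist)
        if not candidates:
            break
        d_min = min(length for length, _, _ in candidates)
        paths = sorted(
            _reconstruct(parent, u, v)
            for length, u, v in candidates
            if length == d_min
        )
        merged_any = False
        for path in paths:
            ra, rb = uf.find(labels[path[0]]), uf.find(labels[path[-1]])
            if ra == rb:
                continue
            uf.union(ra, rb)
            for node in path:
                uf.add(node)
                uf.union(path[0], node)
                forest_nodes.add(node)
            for a, b in zip(path, path[1:]):
                forest_edges.add(canonical_edge(a, b))
            merged_any = True
        if not merged_any:
            break

    main_nodes = _main_component(present, forest_nodes, forest_edges, uf)
    tree_edges = _extract_tree(main_nodes, forest_edges, present)
    main_nodes, tree_edges = _prune_leaf_linkers(main_nodes, tree_edges,
                                                 set(present))

    seed_in = sorted(main_nodes & set(present))
    linker = sorted(main_nodes - set(present))
    excluded = sorted(seeds.genes - set(seed_in))
    return SubnetworkResult(
        seed_nodes=_geneset("seeds", seed_in),
        linker_nodes=_geneset("linkers", linker),
        edges=frozenset(tree_edges),
        excluded_seeds=_geneset("excluded_seeds", excluded),
        is_tree=True,
    )


def _multi_source_bfs(adj, forest_nodes, uf):
    """Label every reachable node with its nearest tree (component root)."""
    labels: dict[str, str] = {}
    dist: dict[str, int] = {}
    parent: dict[str, str | None] = {}
    queue: deque[str] = deque()
    for s in sorted(forest_nodes):
        labels[s] = uf.find(s)
        dist[s] = 0
        parent[s] = None
        queue.append(s)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in labels:
                labels[v] = labels[u]
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
    return labels, dist, parent


def _meeting_candidates(g, labels, dist):
    """Graph edges joining two different BFS regions, with path length."""
    out = []
    for a, b in g.edges:
        la, lb = labels.get(a), labels.get(b)
        if la is None or lb is None or la == lb:
            continue
        out.append((dist[a] + dist[b] + 1, a, b))
    return out


def _reconstruct(parent, u, v) -> tuple[str, ...]:
    """Full node path tree_a ... u - v ... tree_b, canonically oriented."""
    left = []
    x: str | None = u
    while x is not None:
        left.append(x)
        x = parent[x]
    left.reverse()
    right = []
    x = v
    while x is not None:
        right.append(x)
        x = parent[x]
    seq = tuple(left + right)
    rev = tuple(reversed(seq))
    return seq if seq <= rev else rev


def _main_component(present, forest_nodes, forest_edges, uf):
    """Node set of the merged component holding the most seeds."""
    comp_of = {n: uf.find(n) for n in forest_nodes}
    seed_count: dict[str, int] = {}
    for s in present:
        seed_count[comp_of[s]] = seed_count.get(comp_of[s], 0) + 1
    best = min(
        seed_count,
        key=lambda c: (-seed_count[c],
                       min(s for s in present if comp_of[s] == c)),
    )
    return {n for n in forest_nodes if comp_of[n] == best}


def _extract_tree(nodes, edges, present):
    """Deterministic BFS spanning tree of the forest component."""
    if len(nodes) <= 1:
        return set()
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        if a in nodes and b in nodes:
            adj[a].append(b)
            adj[b].append(a)
    for n in adj:
        adj[n].sort()
    root = min(n for n in nodes if n in present)
    tree: set[tuple[str, str]] = set()
    seen = {root}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                tree.add(canonical_edge(u, v))
                queue.append(v)
    return tree


def _prune_leaf_linkers(nodes, edges, seed_set):
    """Iteratively drop non-seed leaves left over from batched merging."""
    nodes = set(nodes)
    edges = set(edges)
    while True:
        degree: dict[str, int] = {n: 0 for n in nodes}
        for a, b in edges:
            degree[a] += 1
            degree[b] += 1
        drop = {n for n in nodes if degree[n] <= 1 and n not in seed_set}
        if not drop:
            return nodes, edges
        nodes -= drop
        edges = {(a, b) for a, b in edges if a not in drop and b not in drop}


def densify(g: Interactome, tree: SubnetworkResult) -> SubnetworkResult:
    """Restore all interactome edges among the subnetwork's nodes.

    Keeps the node set and replaces the edge set with the subgraph of ``g``
    induced on it.  Idempotent; never removes edges of the tree (every tree
    edge is a graph edge).
    """
    nodes = tree.nodes
    missing = nodes - g.nodes
    if missing:
        raise ValueError(f"subnetwork nodes absent from graph: {sorted(missing)[:5]}")
    induced = frozenset(
        e for e in g.edges if e[0] in nodes and e[1] in nodes
    )
    return SubnetworkResult(
        seed_nodes=tree.seed_nodes,
        linker_nodes=tree.linker_nodes,
        edges=induced,
        excluded_seeds=tree.excluded_seeds,
        is_tree=False,
    )


def classify_nodes(result: SubnetworkResult,
                   seeds: GeneSet) -> tuple[list[str], list[str]]:
    """Partition result nodes into (seed list, linker list), sorted."""
    seed_list = sorted(result.nodes & seeds.genes)
    linker_list = sorted(result.nodes - seeds.genes)
    return seed_list, linker_list


def _geneset(name: str, symbols) -> GeneSet:
    gs = GeneSet.__new__(GeneSet)
    object.__setattr__(gs, "name", name)
    object.__setattr__(gs, "genes", frozenset(symbols))
    return gs
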