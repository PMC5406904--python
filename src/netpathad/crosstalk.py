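"""Pathway-crosstalk network construction.

Two enriched pathways "crosstalk" when their disease-set member gene lists
(candidate genes) overlap.  The overlap of a pair (A, B) is scored by the
Jaccard coefficient JC = |A∩B| / |A∪B| and the overlap coefficient
OC = |A∩B| / min(|A|, |B|); the edge score is their average.

The construction cascade:
  1. discard pathways with fewer than ``min_genes`` candidate genes
     (small lists give few or biased connections);
  2. form all unordered pairs of the survivors;
  3. keep pairs sharing at least ``min_shared`` genes;
  4. the network's nodes are the pathways participating in a kept pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .datatypes import GeneSet

__all__ = [
    "CrosstalkEdge",
    "CrosstalkNetwork",
    "jaccard",
    "overlap_coef",
    "build_crosstalk",
    "detect_modules",
]


def jaccard(a: GeneSet, b: GeneSet) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|."""
    union = a.union(b)
    if not union:
        raise ValueError("jaccard undefined for two empty sets")
    return len(a.intersect(b)) / len(union)


def overlap_coef(a: GeneSet, b: GeneSet) -> float:
    """Overlap (Szymkiewicz-Simpson) coefficient |A∩B| / min(|A|, |B|)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap coefficient undefined for an empty set")
    return len(a.intersect(b)) / min(len(a), len(b))


@dataclass(frozen=True)
class CrosstalkEdge:
    """A scored pathway pair sharing candidate genes."""

    pathway_a: str
    pathway_b: str
    shared_genes: GeneSet
    jc: float
    oc: float
    score: float

    def __post_init__(self):
        if self.pathway_a == self.pathway_b:
            raise ValueError("crosstalk edge endpoints must differ")
        if self.jc > self.oc + 1e-12:
            raise ValueError("jc cannot exceed oc")


@dataclass(frozen=True)
class CrosstalkNetwork:
    nodes: tuple[str, ...]
    edges: tuple[CrosstalkEdge, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.pathway_a, e.pathway_b, jc=e.jc, oc=e.oc,
                       score=e.score, n_shared=len(e.shared_genes))
        return g


def build_crosstalk(
    enriched: Sequence[tuple[str, GeneSet]],
    min_genes: int = 6,
    min_shared: int = 2,
) -> CrosstalkNetwork:
    """Build the crosstalk network from (pathway id, candidate GeneSet) pairs.

    Input pathways are assumed to have already passed the enrichment FDR
    gate.  Pathways with fewer than ``min_genes`` candidates are dropped
    first; the shared-gene filter then runs among the survivors only.
    Pathways left without any kept pair do not appear as nodes.
    """
    if min_genes < 1 or min_shared < 1:
        raise ValueError("min_genes and min_shared must be >= 1")
    ids = [pid for pid, _ in enriched]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate pathway ids: {dupes}")

    survivors = sorted(
        ((pid, gs) for pid, gs in enriched if len(gs) >= min_genes),
        key=lambda t: t[0],
    )
    edges: list[CrosstalkEdge] = []
    for (id_a, gs_a), (id_b, gs_b) in combinations(survivors, 2):
        shared = sorted(gs_a.intersect(gs_b))
        if len(shared) < min_shared:
            continue
        jc = jaccard(gs_a, gs_b)
        oc = overlap_coef(gs_a, gs_b)
        edges.append(
            CrosstalkEdge(
                pathway_a=id_a,
                pathway_b=id_b,
                shared_genes=GeneSet(f"{id_a}|{id_b}", shared),
                jc=jc, oc=oc, score=(jc + oc) / 2.0,
            )
        )
    nodes = sorted({e.pathway_a for e in edges} | {e.pathway_b for e in edges})
    return CrosstalkNetwork(nodes=tuple(nodes), edges=tuple(edges))


def size_filter_count(enriched: Sequence[tuple[str, GeneSet]],
                      min_genes: int = 6) -> int:
    """Number of pathways whose candidate list meets the size threshold."""
    return sum(1 for _, gs in enriched if len(gs) >= min_genes)


def detect_modules(net: CrosstalkNetwork, seed: int = 0) -> list[set[str]]:
    """Partition the crosstalk network into modules.

    Greedy modularity maximization on score-weighted edges.  The published
    three-module grouping of the source network was visual/manual, so this
    partition is a descriptive aid, not a reproduction target.  Deterministic
    for a given network (the algorithm itself is seed-free; ``seed`` is
    accepted for interface symmetry).
    """
    if net.n_nodes == 0:
        raise ValueError("cannot partition an empty network")
    import networkx as nx

    g = net.to_networkx()
    communities = nx.algorithms.community.greedy_modularity_communities(
        g, weight="score"
    )
    parts = [set(c) for c in communities]
    parts.sort(key=lambda s: (-len(s), min(s)))
    return parts
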