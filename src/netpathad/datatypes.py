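"""Core domain types shared across the pipeline.

Gene symbols are normalized once, at construction time: upper-cased,
whitespace-trimmed, empty strings rejected.  Interactome edges are stored in
canonical (lexicographically sorted) orientation so that deduplication and
serialization are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GeneSet",
    "PathwayRecord",
    "EnrichedPathwayTable",
    "Interactome",
    "canonical_edge",
    "normalize_symbol",
]


def normalize_symbol(symbol: str) -> str:
    """Trim and upper-case a gene symbol; reject empty results."""
    s = symbol.strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique, normalized gene symbols."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Iterable[str]):
        if not name:
            raise ValueError("GeneSet name must be non-empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in genes)
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))

    def intersect(self, other: "GeneSet") -> frozenset[str]:
        return self.genes & other.genes

    def union(self, other: "GeneSet") -> frozenset[str]:
        return self.genes | other.genes


@dataclass(frozen=True)
class PathwayRecord:
    """One pathway / gene set from a GMT-style database."""

    pathway_id: str
    display_name: str
    members: GeneSet
    source: str = ""

    def __post_init__(self):
        if not self.pathway_id:
            raise ValueError("pathway_id must be non-empty")
        if len(self.members) == 0:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


@dataclass(frozen=True)
class EnrichedPathwayRecord:
    """One enriched pathway with its disease-set member genes and p-values."""

    pathway_name: str
    candidates: GeneSet
    p_raw: float
    p_bh: float

    def __post_init__(self):
        if not (0.0 < self.p_raw <= self.p_bh <= 1.0):
            raise ValueError(
                f"invalid p-values for {self.pathway_name!r}: "
                f"p={self.p_raw}, p_bh={self.p_bh}"
            )


@dataclass(frozen=True)
class EnrichedPathwayTable:
    """The packaged table of enriched pathways with candidate-gene lists."""

    records: tuple[EnrichedPathwayRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EnrichedPathwayRecord]:
        return iter(self.records)

    def candidate_sets(self) -> list[tuple[str, GeneSet]]:
        """(pathway name, candidate GeneSet) pairs, in table order."""
        return [(r.pathway_name, r.candidates) for r in self.records]

    def get(self, pathway_name: str) -> EnrichedPathwayRecord:
        for r in self.records:
            if r.pathway_name == pathway_name:
                return r
        raise KeyError(pathway_name)


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) orientation of an undirected edge."""
    return (a, b) if a <= b else (b, a)


class Interactome:
    """An undirected simple graph over gene symbols.

    Self-loops are dropped at insertion; (a, b) and (b, a) collapse onto the
    canonical sorted pair.  Isolated nodes are representable (the node set is
    maintained independently of the edge set).
    """

    __slots__ = ("_nodes", "_edges")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ):
        self._nodes: set[str] = set()
        self._edges: set[tuple[str, str]] = set()
        for n in nodes:
            self._nodes.add(normalize_symbol(n))
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: str, b: str) -> None:
        a, b = normalize_symbol(a), normalize_symbol(b)
        self._nodes.add(a)
        self._nodes.add(b)
        if a == b:
            return  # self-loop: node kept, edge dropped
        self._edges.add(canonical_edge(a, b))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def adjacency(self) -> dict[str, list[str]]:
        """Adjacency lists with deterministically sorted neighbors."""
        adj: dict[str, list[str]] = {n: [] for n in self._nodes}
        for a, b in self._edges:
            adj[a].append(b)
            adj[b].append(a)
        for n in adj:
            adj[n].sort()
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, g) -> "Interactome":
        return cls(edges=g.edges(), nodes=g.nodes())
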