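"""Merging and summarizing protein-protein interaction networks.

Multiple edge-list sources (e.g. a primary interaction database export plus
a secondary literature-derived interactome) are merged with set semantics:
the node set is the union of all endpoints, self-interactions are excluded,
and redundant pairs — including reversed duplicates — collapse to one
undirected edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import Interactome

__all__ = ["merge_interactomes", "network_summary", "NetworkSummary"]


def merge_interactomes(sources: Sequence[Interactome]) -> Interactome:
    """Union of interactomes (commutative, associative, idempotent)."""
    if len(sources) == 0:
        raise ValueError("need at least one interactome to merge")
    merged = Interactome()
    nodes: set[str] = set()
    for src in sources:
        nodes |= src.nodes
        for a, b in src.edges:
            merged.add_edge(a, b)
    # preserve isolated nodes declared by any source
    return Interactome(edges=merged.edges, nodes=nodes)


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    degree_quantiles: tuple[float, ...]  # 0, 25, 50, 75, 100th percentiles
    component_sizes: tuple[int, ...]     # descending

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)

    @property
    def largest_component_fraction(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        return self.component_sizes[0] / self.n_nodes


def network_summary(net: Interactome) -> NetworkSummary:
    """Node/edge counts, degree quantiles and component sizes."""
    if net.n_nodes == 0:
        return NetworkSummary(0, 0, (0.0,) * 5, ())
    degrees = {n: 0 for n in net.nodes}
    for a, b in net.edges:
        degrees[a] += 1
        degrees[b] += 1
    quant = tuple(
        float(q)
        for q in np.percentile(list(degrees.values()), [0, 25, 50, 75, 100])
    )
    comp_sizes = tuple(
        sorted((len(c) for c in _components(net)), reverse=True)
    )
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        degree_quantiles=quant,
        component_sizes=comp_sizes,
    )


def _components(net: Interactome):
    adj = net.adjacency()
    seen: set[str] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        yield comp
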