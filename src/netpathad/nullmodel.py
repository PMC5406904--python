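"""Erdős–Rényi G(n, m) null ensembles for network non-randomness tests.

An observed network is compared against random simple graphs with exactly
the same number of nodes and edges (the G(n, m) model — "same number of
vertices and interactions").  For each topological statistic the report
carries the observed value, the null mean and standard deviation, a
z-score, and a two-sided empirical p value with the add-one rule
p = (r + 1) / (R + 1), which cannot reach zero at finite ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .datatypes import Interactome

__all__ = [
    "NullEnsembleSpec",
    "generate_gnm",
    "compare_to_null",
    "STATISTICS",
    "NullComparison",
]


@dataclass(frozen=True)
class NullEnsembleSpec:
    n_nodes: int
    n_edges: int
    n_replicates: int
    rng_seed: int

    def __post_init__(self):
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not (0 <= self.n_edges <= max_edges):
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for n_nodes={self.n_nodes} "
                f"(max {max_edges})"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_gnm(spec: NullEnsembleSpec) -> Iterator[Interactome]:
    """Stream ``n_replicates`` uniform G(n, m) graphs, reproducibly seeded.

    Node labels are synthetic symbols ``N00000`` ... so replicates slot into
    any Interactome-consuming code path.
    """
    rng = np.random.default_rng(spec.rng_seed)
    labels = {i: f"N{i:05d}" for i in range(spec.n_nodes)}
    for _ in range(spec.n_replicates):
        g = nx.gnm_random_graph(spec.n_nodes, spec.n_edges, seed=rng)
        yield Interactome(
            edges=((labels[a], labels[b]) for a, b in g.edges()),
            nodes=labels.values(),
        )


# ---------------------------------------------------------------------------
# topological statistics


def _clustering(g: nx.Graph) -> float:
    """Global clustering coefficient (transitivity)."""
    return float(nx.transitivity(g))


def _largest_component(g: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    return g.subgraph(comp)


def _mean_shortest_path(g: nx.Graph) -> float:
    """Mean pairwise shortest-path length on the largest component."""
    if g.number_of_nodes() == 0:
        return float("nan")
    sub = _largest_component(g)
    n = sub.number_of_nodes()
    if n < 2:
        return 0.0
    adj = nx.to_scipy_sparse_array(sub, format="csr", dtype=np.int8)
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    return float(d[np.triu_indices(n, k=1)].mean())


def _largest_component_fraction(g: nx.Graph) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    return _largest_component(g).number_of_nodes() / g.number_of_nodes()


def _assortativity(g: nx.Graph) -> float:
    """Degree assortativity; NaN on degenerate degree sequences."""
    if g.number_of_edges() == 0:
        return float("nan")
    with np.errstate(all="ignore"):
        return float(nx.degree_assortativity_coefficient(g))


STATISTICS = {
    "clustering": _clustering,
    "mean_shortest_path": _mean_shortest_path,
    "largest_component_fraction": _largest_component_fraction,
    "assortativity": _assortativity,
}


@dataclass(frozen=True)
class NullComparison:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_replicates: int


def compare_to_null(
    observed: Interactome,
    spec: NullEnsembleSpec,
    statistics: Sequence[str] | None = None,
) -> list[NullComparison]:
    """Compare an observed network to its size-matched G(n, m) ensemble.

    The empirical p is two-sided: r counts replicates whose statistic lies
    at least as far from the null mean as the observed value does.
    Replicates where a statistic is undefined (NaN) are excluded from that
    statistic's tally.
    """
    names = list(statistics) if statistics is not None else list(STATISTICS)
    unknown = [s for s in names if s not in STATISTICS]
    if unknown:
        raise ValueError(
            f"unknown statistics {unknown}; available: {sorted(STATISTICS)}"
        )
    g_obs = observed.to_networkx()
    obs = {s: STATISTICS[s](g_obs) for s in names}
    null_vals: dict[str, list[float]] = {s: [] for s in names}
    for replicate in generate_gnm(spec):
        g = replicate.to_networkx()
        for s in names:
            null_vals[s].append(STATISTICS[s](g))

    out = []
    for s in names:
        vals = np.asarray(null_vals[s], dtype=float)
        ok = vals[~np.isnan(vals)]
        mean = float(ok.mean()) if ok.size else float("nan")
        sd = float(ok.std(ddof=1)) if ok.size > 1 else float("nan")
        z = (obs[s] - mean) / sd if sd and sd > 0 else float("nan")
        if ok.size and not np.isnan(obs[s]):
            r = int(np.sum(np.abs(ok - mean) >= abs(obs[s] - mean)))
            p = (r + 1) / (ok.size + 1)
        else:
            p = float("nan")
        out.append(
            NullComparison(
                statistic=s, observed=float(obs[s]), null_mean=mean,
                null_sd=sd, z=float(z), p_empirical=float(p),
                n_replicates=int(ok.size),
            )
        )
    return out
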