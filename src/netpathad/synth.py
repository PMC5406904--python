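"""Synthetic-data generators with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and seed:

* ``make_universe`` — an indexed gene universe (symbols are index-based and
  independent of the seed, so different draws share one namespace);
* ``make_pathway_db`` — pathway memberships with controlled pairwise overlap
  through a common shared pool;
* ``make_query`` — a query gene set with a planted enrichment signal (a
  stated fraction drawn from target pathways);
* ``make_interactome`` — a G(n, m) (or preferential-attachment) background
  with optional planted linker paths between designated seed genes, the
  structure the Steiner step is designed to recover.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np

from .datatypes import GeneSet, Interactome, PathwayRecord

__all__ = ["make_universe", "make_pathway_db", "make_query", "make_interactome"]


def _symbol(i: int) -> str:
    return f"G{i:06d}"


def make_universe(n_genes: int, seed: int = 0) -> GeneSet:
    """Universe of ``n_genes`` synthetic symbols G000001... (seed-independent)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return GeneSet("universe", (_symbol(i) for i in range(1, n_genes + 1)))


def make_pathway_db(
    universe: GeneSet,
    n_pathways: int,
    size_range: tuple[int, int],
    overlap_frac: float,
    seed: int,
    pool_size: int | None = None,
    disjoint: bool = False,
) -> list[PathwayRecord]:
    """Sample pathways with controlled pairwise sharing.

    A fraction ``overlap_frac`` of each pathway is drawn from a common
    shared pool (default size: the largest pathway size); the remainder is
    drawn from the rest of the universe.  ``disjoint=True`` instead samples
    all pathways without replacement from the universe, guaranteeing empty
    pairwise intersections.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid size_range {size_range}")
    if not (0.0 <= overlap_frac <= 1.0):
        raise ValueError("overlap_frac must be in [0, 1]")
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    genes = sorted(universe.genes)
    rng = np.random.default_rng(seed)

    if disjoint:
        if n_pathways * hi > len(genes):
            raise ValueError(
                f"disjoint sampling needs {n_pathways * hi} genes, "
                f"universe has {len(genes)}"
            )
        shuffled = list(rng.permutation(genes))
        records = []
        cursor = 0
        for i in range(n_pathways):
            size = int(rng.integers(lo, hi + 1))
            members = shuffled[cursor:cursor + size]
            cursor += size
            records.append(_record(i, members))
        return records

    pool_size = pool_size if pool_size is not None else hi
    if pool_size > len(genes):
        raise ValueError("pool_size exceeds universe")
    pool = sorted(rng.choice(genes, size=pool_size, replace=False))
    outside = sorted(set(genes) - set(pool))
    records = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = round(overlap_frac * size)
        n_shared = min(n_shared, pool_size)
        n_rest = size - n_shared
        if n_rest > len(outside):
            raise ValueError("universe too small for requested pathway sizes")
        members = list(rng.choice(pool, size=n_shared, replace=False))
        members += list(rng.choice(outside, size=n_rest, replace=False))
        records.append(_record(i, members))
    return records


def _record(i: int, members: Sequence[str]) -> PathwayRecord:
    name = f"PW{i + 1:03d}"
    return PathwayRecord(
        pathway_id=name,
        display_name=name,
        members=GeneSet(name, members),
        source="synthetic",
    )


def make_query(
    universe: GeneSet,
    target_pathways: Sequence[PathwayRecord],
    n_query: int,
    planted_frac: float,
    seed: int,
    background: str = "complement",
) -> GeneSet:
    """A query set with ``planted_frac`` of its genes from the targets.

    The planted portion is drawn uniformly from the union of target
    memberships.  The remainder is drawn from ``background``:
    ``"complement"`` (default) samples the rest of the universe only, so
    the planted count is exact; ``"universe"`` samples the whole universe
    minus already-picked genes, the right null when calibrating type-I
    behaviour with ``planted_frac=0`` (chance overlap stays possible).
    """
    if not (0.0 <= planted_frac <= 1.0):
        raise ValueError("planted_frac must be in [0, 1]")
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    if background not in ("complement", "universe"):
        raise ValueError(f"unknown background mode {background!r}")
    target: set[str] = set()
    for rec in target_pathways:
        target |= rec.members.genes & universe.genes
    n_planted = round(planted_frac * n_query)
    if n_planted > len(target):
        raise ValueError(
            f"planted_frac requires {n_planted} target genes, "
            f"targets hold {len(target)}"
        )
    rng = np.random.default_rng(seed)
    picked = list(rng.choice(sorted(target), size=n_planted, replace=False))
    if background == "complement":
        pool = sorted(universe.genes - target)
    else:
        pool = sorted(universe.genes - set(picked))
    n_rest = n_query - n_planted
    if n_rest > len(pool):
        raise ValueError("universe too small for requested query size")
    picked += list(rng.choice(pool, size=n_rest, replace=False))
    return GeneSet("query", picked)


def make_interactome(
    n_nodes: int,
    n_edges: int,
    planted_paths: Sequence[tuple[str, str, int]] = (),
    seed: int = 0,
    model: str = "gnm",
) -> Interactome:
    """A synthetic interactome: random background plus planted linker paths.

    The background is G(n, m) by default (``model="pa"`` gives a
    Barabási–Albert preferential-attachment graph with mean degree
    2·m/n, for heavy-tailed degree sequences).  Background nodes are the
    first ``n_nodes`` universe symbols.  Each planted path adds a simple
    chain of ``path_length`` edges between two named endpoints through
    fresh linker nodes ``L0001``, ``L0002``, ...; endpoints absent from the
    background are added.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValueError(f"n_edges={n_edges} infeasible for n_nodes={n_nodes}")
    rng = np.random.default_rng(seed)
    if model == "gnm":
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=rng)
    elif model == "pa":
        m_attach = max(1, round(n_edges / max(n_nodes, 1)))
        g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=rng)
    else:
        raise ValueError(f"unknown background model {model!r}")

    labels = {i: _symbol(i + 1) for i in range(n_nodes)}
    net = Interactome(
        edges=((labels[a], labels[b]) for a, b in g.edges()),
        nodes=labels.values(),
    )
    linker_counter = 0
    nodes = set(net.nodes)
    for a, b, length in planted_paths:
        if length < 1:
            raise ValueError("planted path length must be >= 1")
        chain = [a]
        for _ in range(length - 1):
            linker_counter += 1
            chain.append(f"L{linker_counter:04d}")
        chain.append(b)
        for u, v in zip(chain, chain[1:]):
            net.add_edge(u, v)
        nodes |= set(chain)
    return Interactome(edges=net.edges, nodes=nodes | set(net.nodes))
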