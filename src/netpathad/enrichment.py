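"""Gene-set over-representation analysis.

One-sided hypergeometric test (equivalent to a one-sided Fisher exact test
on the 2x2 overlap table) of a query gene set against each pathway of a
database, with Benjamini-Hochberg control of the false discovery rate
across all tested pathways.

The sampling model: the universe holds ``N`` genes, ``K`` of which belong
to the pathway; drawing the ``n`` query genes at random, the overlap ``k``
is hypergeometric, and the reported p value is the upper tail
``P(X >= k)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSet, PathwayRecord

__all__ = ["EnrichmentResult", "hypergeom_tail", "bh_adjust", "enrich"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway over-representation outcome."""

    pathway_id: str
    display_name: str
    k: int          # query ∩ pathway, within the universe
    K: int          # pathway size within the universe
    n: int          # query size within the universe
    N: int          # universe size
    overlap_genes: GeneSet
    p_raw: float
    p_bh: float
    significant: bool

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"{self.pathway_id}: overlap k={self.k} outside "
                f"[0, min(K={self.K}, n={self.n})]"
            )
        if self.k != len(self.overlap_genes):
            raise ValueError(f"{self.pathway_id}: k != |overlap_genes|")
        if not (0.0 < self.p_raw <= self.p_bh <= 1.0):
            raise ValueError(
                f"{self.pathway_id}: need 0 < p_raw <= p_bh <= 1, "
                f"got {self.p_raw}, {self.p_bh}"
            )


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` pathway genes in the universe, ``n`` query
    genes drawn, ``k`` observed overlap.
    """
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("hypergeometric parameters must be non-negative")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N, got K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, in input order.

    Each output is >= its input, capped at 1, and monotone along the sorted
    p-value order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def enrich(
    query: GeneSet,
    db: Sequence[PathwayRecord],
    universe: GeneSet | None = None,
    fdr_threshold: float = 0.05,
    keep_empty: bool = False,
) -> list[EnrichmentResult]:
    """Test every pathway in ``db`` for over-representation in ``query``.

    The universe defaults to the union of all pathway members.  Query genes
    outside the universe are dropped (with a logged count); pathway
    memberships are restricted to the universe.  BH adjustment runs across
    ALL tested pathways, including zero-overlap ones; by default only
    pathways with overlap k >= 1 are returned (``keep_empty`` returns all).

    Results are sorted by raw p value, ties broken by pathway id.
    """
    if not (0.0 < fdr_threshold < 1.0):
        raise ValueError(f"fdr_threshold must be in (0, 1), got {fdr_threshold}")
    if len(db) == 0:
        raise ValueError("empty pathway database")
    if universe is None:
        members: set[str] = set()
        for rec in db:
            members |= rec.members.genes
        universe = GeneSet("universe", members)
    if len(universe) == 0:
        raise ValueError("empty universe")

    query_in = query.genes & universe.genes
    dropped = len(query.genes) - len(query_in)
    if dropped:
        log.info("enrich: dropped %d query genes outside the universe", dropped)
    if not query_in:
        raise ValueError("no query genes inside the universe")

    N = len(universe)
    n = len(query_in)
    rows = []
    for rec in db:
        pathway_in = rec.members.genes & universe.genes
        overlap = sorted(pathway_in & query_in)
        rows.append((rec, len(overlap), len(pathway_in), overlap))

    p_raws = [hypergeom_tail(k, K, n, N) for _, k, K, _ in rows]
    p_bhs = bh_adjust(p_raws)

    results = []
    for (rec, k, K, overlap), p_raw, p_bh in zip(rows, p_raws, p_bhs):
        if k == 0 and not keep_empty:
            continue
        results.append(
            EnrichmentResult(
                pathway_id=rec.pathway_id,
                display_name=rec.display_name,
                k=k, K=K, n=n, N=N,
                overlap_genes=GeneSet(rec.pathway_id, overlap)
                if overlap else _empty_geneset(rec.pathway_id),
                p_raw=p_raw,
                p_bh=p_bh,
                significant=bool(p_bh < fdr_threshold),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return results


def _empty_geneset(name: str) -> GeneSet:
    gs = GeneSet.__new__(GeneSet)
    object.__setattr__(gs, "name", name)
    object.__setattr__(gs, "genes", frozenset())
    return gs
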