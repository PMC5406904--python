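"""Independent brute-force oracles used to check the library's fast paths.

Everything here is deliberately naive: exact integer arithmetic for the
hypergeometric tail, a literal step-up loop for Benjamini-Hochberg, a
double loop over all pathway pairs for crosstalk edges, and exhaustive
bitmask enumeration of connected node subsets for optimal Steiner trees.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by summing C(K,i)*C(N-K,n-i) terms exactly."""
    num = sum(comb(K, i) * comb(N - K, n - i)
              for i in range(k, min(K, n) + 1))
    return num / comb(N, n)


def hypergeom_tails_all_k(K: int, n: int, N: int) -> list[float]:
    """Exact P(X >= k) for every k = 0..min(K, n), via one cumulative pass."""
    kmax = min(K, n)
    den = comb(N, n)
    tails = [0.0] * (kmax + 1)
    acc = 0
    for k in range(kmax, -1, -1):
        acc += comb(K, k) * comb(N - K, n - k)
        tails[k] = acc / den
    return tails


def bh_stepup(p_values: list[float]) -> list[float]:
    """Literal BH step-up: sort, multiply by m/rank, cumulative minimum."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def crosstalk_edges_bruteforce(sets, min_genes, min_shared):
    """All pathway pairs surviving the cascade, by direct double loop."""
    kept = [(pid, gs) for pid, gs in sets if len(gs) >= min_genes]
    out = set()
    for i in range(len(kept)):
        for j in range(len(kept)):
            if i >= j:
                continue
            a, b = kept[i], kept[j]
            if len(a[1].genes & b[1].genes) >= min_shared:
                out.add(tuple(sorted((a[0], b[0]))))
    return out


def connected_subsets(n: int, edges: list[tuple[int, int]]) -> list[int]:
    """Bitmasks of all connected non-empty node subsets of a small graph."""
    adj = [0] * n
    for a, b in edges:
        adj[a] |= 1 << b
        adj[b] |= 1 << a
    result = []
    for mask in range(1, 1 << n):
        start = (mask & -mask).bit_length() - 1
        seen = 1 << start
        frontier = seen
        while frontier:
            nxt = 0
            m = frontier
            while m:
                v = (m & -m).bit_length() - 1
                m &= m - 1
                nxt |= adj[v] & mask & ~seen
            seen |= nxt
            frontier = nxt
        if seen == mask:
            result.append(mask)
    return result


def optimal_steiner_size(conn_masks: list[int], seed_mask: int) -> int | None:
    """Minimal node count of a connected subgraph containing all seeds."""
    best = None
    for mask in conn_masks:
        if mask & seed_mask == seed_mask:
            size = mask.bit_count()
            if best is None or size < best:
                best = size
    return best
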