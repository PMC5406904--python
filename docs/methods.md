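# Methods

## Over-representation analysis

A query gene set is tested against each pathway of a GMT database with the
one-sided hypergeometric tail P(X ≥ k), the distribution of the overlap k
between an n-gene query and a K-gene pathway under uniform sampling from
an N-gene universe. This equals the one-sided Fisher exact test on the
2×2 overlap table. Implementation: `scipy.stats.hypergeom.sf(k-1, N, K, n)`;
the test suite checks it against exact integer-arithmetic summation over
the full N ≤ 60 grid to a relative tolerance of 1e-10.

**Universe.** Web enrichment services use internal, undocumented
backgrounds, so exact published p-values are not reproducible and are not
targeted. The default universe is the union of all pathway memberships in
the loaded database — self-contained and conventional — and an explicit
universe file can override it. Query genes outside the universe are
dropped with a logged count so the 2×2 table stays coherent.

**Multiple testing.** Benjamini–Hochberg step-up adjustment
(`statsmodels.stats.multitest.multipletests`, checked against a literal
step-up oracle) runs across *all* tested pathways, including zero-overlap
ones — standard FDR semantics. Pathways are reported when k ≥ 1 and
flagged significant at FDR < 0.05 (configurable). No minimum-overlap gate
is applied before testing.

## Pathway crosstalk

The crosstalk measure operates on *candidate genes* — each pathway's
intersection with the disease gene set — not on full pathway memberships:
the candidate lists are what the packaged pathway table prints, and they
are what the published network was built from. For a pair (A, B):
JC = |A∩B|/|A∪B|, OC = |A∩B|/min(|A|,|B|), edge score (JC+OC)/2. JC ≤ OC
always, so the score lies between them.

The cascade order matters: first drop pathways with fewer than
`min_genes = 6` candidates, *then* apply the `min_shared = 2` pair filter
among the survivors. Only this order reproduces the published cascade
(68 enriched pathways → 41 past the size filter → 37 pathways joined by
207 crosstalks). Pathway display names are the node keys; duplicate names
error.

`detect_modules` (greedy modularity maximization on score-weighted edges,
networkx implementation, deterministic for a given network) is a
descriptive aid: the published three-module grouping was drawn manually,
so the partition is reported but is not a reproduction target. On the
packaged table it yields four modules whose contents align with the
published immune / neuronal–metabolic / growth–endocrine themes.

## Interactome compilation

Edge-list sources (two-column TSV or SIF) merge with set semantics:
self-interactions dropped, reversed duplicates collapsed onto
lexicographically canonical pairs, node set the union of endpoints (plus
declared isolated nodes). Merging is commutative, associative and
idempotent; all tested as properties. Identifier mapping is upstream of
this package — inputs must already carry gene symbols, which are
upper-cased and trimmed at every ingestion point.

The published compilation (16,022 proteins, 228,122 interactions) is a
supplementary download; the packaged tests and the acceptance script
exercise parsing, merging and downstream analysis on synthetic
interactomes generated at exactly that scale instead.

## Steiner subnetwork

Seeds are connected by the classic greedy tree-merging heuristic on an
unweighted graph (hop-count shortest paths): start with one singleton tree
per seed, repeatedly merge the closest pair of trees along a shortest
path, absorbing interior nodes as linkers, until one tree spans each
seed-reachable component. The result is restricted to the component
holding the most seeds; unreachable or lone seeds are listed as excluded.

*Batched rounds.* Each round runs one multi-source BFS labelling every
node with its nearest tree, then merges **all** inter-tree connections
realizable at that round's minimal hop distance, in canonical-path order
under union-find. This keeps the cost at O(rounds × |E|) — a few BFS
sweeps even on a 228k-edge interactome — instead of one BFS per merge.
The final structure is reduced to a deterministic BFS spanning tree and
non-seed leaves are pruned. The metric-closure argument for the classic
heuristic carries over: every merge costs no more than the corresponding
closure-MST edge, so the tree spans at most 2·OPT − 1 nodes; on
tree-shaped hosts the connection paths are unique and the result is
exactly optimal. Both bounds are verified exhaustively against a bitmask
enumeration oracle on every connected graph with up to 7 nodes (the full
graph atlas) with all seed subsets of sizes 1–4, and on seeded random
graphs and trees with 8–9 nodes.

*Tie-breaking* is total and lexicographic — BFS expands sorted
adjacencies, and candidate paths merge in canonical (orientation-
normalized) sequence order — so identical inputs, regardless of edge
insertion order, give identical outputs.

*Densification.* A tree on V nodes has |V|−1 edges; published disease
subnetworks of this kind report far more edges than nodes-minus-one, which
is consistent with restoring all interactome edges among the chosen nodes.
`densify` therefore returns the induced subgraph on the tree's node set
and the pipeline applies it by default (flag to disable). This reading is
an inference; the bare tree remains available.

## Null model

G(n, m) — uniform over simple graphs with exactly n nodes and m edges —
rather than G(n, p), because the comparison demands the same number of
vertices and interactions exactly. Statistics: global clustering
coefficient (transitivity), mean shortest path on the largest component
(scipy csgraph BFS), largest-component fraction, degree assortativity
(NaN on degenerate degree sequences; NaN replicates are excluded from
that statistic's tally). Empirical p uses the add-one rule
p = (r+1)/(R+1) with r the number of replicates at least as far from the
null mean as the observation (two-sided), so p ∈ [1/(R+1), 1] and can
never be zero at finite R. The ensemble default is 1000 replicates; the
calibration self-tests and the acceptance script use 200-replicate
ensembles, which already pin the null mean of the statistics used to well
under the assertion margins.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate
exactly the structure each stage assumes:

- **Universe** — indexed symbols `G000001…`; the symbol set is
  deliberately seed-independent so draws from different seeds share one
  namespace.
- **Pathway database** — a fraction `overlap_frac` of each pathway is
  drawn from a common shared pool (pool size defaults to the largest
  pathway size), the rest from the remaining universe; mean pairwise JC
  rises monotonically with `overlap_frac` (verified over 100 seeded
  draws). A `disjoint` mode samples without replacement for guaranteed
  empty intersections.
- **Query** — `planted_frac` of the query comes uniformly from the target
  pathways' members. The remainder comes from the target *complement* by
  default, which makes the planted count exact; for null calibration the
  `background="universe"` mode draws the remainder from the whole
  universe, so chance overlap stays possible and the type-I rate is a
  meaningful ~5% rather than an artifactual 0.
- **Interactome** — G(n, m) background (preferential attachment available
  for heavy-tailed degrees, unused by the tests) plus planted simple
  chains of fresh low-degree linker nodes between designated seeds. With
  a sparse background (n = 300, m = 300, chains of length 3) the planted
  linkers are almost always the unique shortest connections, and the
  heuristic recovers ≥ 90% of them across 50 seeded replicates.

Calibration conditions used throughout: 2000-gene universe, one 50-gene
pathway, 100-gene query with 30 planted genes (effect arm) or a uniform
draw (null arm), 200 replicates per arm, FDR 0.05.

**What the synthetic data does not capture.** Real pathway databases have
hierarchical, heavy-tailed overlap structure rather than a single shared
pool; real interactomes are scale-free with dense cores, study bias and
false positives; and real disease gene lists carry curation noise and
alias ambiguity. Passing these tests shows the machinery is correct under
its stated model, not that the biological conclusions of any particular
dataset are robust. The published-scale runs additionally stand in for
unavailable supplementary data: a G(n, m) graph at 16,022 / 228,122 with
430 embedded seeds has a giant component covering essentially all nodes,
so seed coverage there is ~100%, comfortably above the 0.85 bound but not
evidence about any real interactome's coverage (published value: 91.4%).

## Numerical and degenerate-input choices

- Gene symbols: upper-cased, whitespace-trimmed, empty rejected; files are
  UTF-8; header skipping is an explicit flag (silent autodetection risks
  misparses).
- Edges: canonical lexicographic orientation everywhere, giving
  deterministic serialization and dedup.
- Empty gene list, empty universe, empty pathway database, zero seeds in
  the graph, zero null replicates: all hard errors with specific messages.
  Empty edge-list files parse to empty networks (not errors).
- p-values: enrichment p_raw > 0 always (tail includes the observed
  term); BH inputs restricted to (0, 1].
- The packaged 430-gene seed list is a synthetic stand-in (marked in file
  and docstring): all disease-set symbols printed in the source text plus
  `SYNAD…` placeholders up to the published count.

## Known limitations

- The Steiner heuristic guarantees the 2·OPT − 1 node bound but not
  optimality on general graphs; different tie-breaking (e.g. other tools'
  unspecified orders) can produce different, equally valid subnetworks, so
  exact published node/edge counts are not reproducible targets.
- Enrichment p-values depend on the background universe; published values
  from web services with internal backgrounds cannot be matched exactly.
- `detect_modules` depends on the community-detection algorithm; only the
  qualitative grouping is meaningful.
- The null ensemble matches size only; degree-preserving (configuration
  model) nulls are out of scope.
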