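# Methods

This note documents the algorithms, conventions and design decisions
behind `netpharm`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Network construction and cleaning

The pipeline consumes weighted undirected edge lists (TSV: `a`, `b`,
confidence ∈ [0, 1]; SIF accepted with a caller-supplied default
confidence). Cleaning enforces a simple graph:

- self-loops are dropped at parse time (database exports can contain
  them, and the vertex-weighting scheme below assumes loop-free
  neighbourhood density);
- duplicate edges, in either orientation, collapse to the **maximum**
  confidence — conservative under a "keep confidence > t" filter;
- the confidence filter uses a **strict** inequality (`> 0.7` by
  default, the conventional "high confidence" cut for STRING-style
  combined scores rescaled to [0, 1]);
- nodes left isolated by filtering are removed (the network viewers this
  replaces behave the same way); a flag retains them.

Node identity is the case-preserved identifier string; alias/case
reconciliation happens only in the identifier-normalisation step, never
in the graph layer. The canonical writer emits a 3-column TSV sorted by
endpoint pair, with confidences at full float precision, so
read → write → read is the identity.

## Centralities

Three centralities are computed, with the conventions of the standard
network-analysis tooling this package replaces:

- **degree**: raw neighbour count (an integer, not divided by n−1);
- **closeness**: per connected component, `(m−1)/Σ d(v,u)`; isolated
  nodes score 0. Harmonic closeness is deliberately not used;
- **betweenness**: Brandes' algorithm, endpoints excluded, normalised by
  `2/((m−1)(m−2))` with m the component size (components smaller than 3
  score 0). Whole-graph normalisation and raw values are available by
  flag, because published analyses are often ambiguous about which the
  GUI used.

Shortest-path computations run through networkx; the per-component
normalisation is applied on top of the unnormalised Brandes output. Nodes
are iterated in sorted order so floating-point accumulation is
reproducible bit-for-bit. The test suite checks betweenness against an
independent all-shortest-path enumeration oracle on dozens of random
graphs.

## Hub selection

A two-stage rule:

1. **candidates** — the intersection of the three top-20% lists
   (⌈0.20·n⌉ nodes per centrality). Intersection rather than union is
   used because a union of 20% filters could never produce the small
   candidate sets such analyses report (tens of genes out of ~900, i.e.
   ~3%);
2. **hubs** — the intersection of the three top-k lists, k = 20.

Rankings sort by value descending with lexicographic identifier as the
tie-break and cut at exactly ⌈fraction·n⌉ or k entries — reproducible by
construction. A `ties="all"` mode extends the cut through ties instead.
Ceiling (not floor) keeps small networks from producing empty lists.

## MCODE

Implemented from the published algorithm:

- **vertex weighting**: `w(v) = k_max(N[v]) · density(highest k-core of
  N[v])` over the closed neighbourhood N[v]; nodes with degree below the
  degree cut-off weigh 0. Density is loop-free, `2E/(n(n−1))`. The
  k-core routine is an iterative minimum-degree pruning to fixpoint,
  written in-package and cross-checked against both a naive
  repeated-deletion oracle and networkx;
- **growth**: seeds are taken in decreasing weight (ties broken by
  identifier — the original plugin's order is implementation-defined, so
  a deterministic rule was chosen); breadth-first inclusion of
  neighbours with `w ≥ w_seed·(1 − node_score_cutoff)`, at most
  `max_depth` levels from the seed (seed = depth 0). A node can join at
  most one complex; zero-weight nodes can neither seed nor join;
- **post-processing**: complexes without a k-core at the configured k
  (default 2) are discarded; optional *fluff* (add boundary nodes whose
  closed-neighbourhood density exceeds the fluff cut-off; may overlap
  complexes) runs before optional *haircut* (iteratively strip members
  with < 2 intra-complex links);
- **score**: `density × n = 2E/(n−1)`; complexes are ranked by score,
  then size, then seed.

Defaults — degree cut-off 4, node score cut-off 0.2, k-core 2, haircut
off, fluff off, max depth 100 — are the standard configuration for PPI
module detection. "Haircut off" is taken literally; since GUI defaults
commonly enable haircut, both behaviours are implemented and tested.

Scoring note: with 2 d.p. half-up rounding the formula gives 22.59 for a
(79 nodes, 881 edges) module and 18.79 for (44, 404), but 9.8966 → 9.90
for (59, 287); reference values quoted elsewhere at 9.89 reflect
truncation in display. The package always returns the exact value and
leaves formatting to the caller.

## Set operations and coverage

Identifier normalisation substitutes canonical accessions from a
two-column mapping table; aliases mapping to one accession merge, and
unmapped identifiers are **kept** verbatim (conservative set sizes) and
reported — a strict mode drops them. A mapping with conflicting duplicate
keys is an error. Venn partitions (2- and 3-way) are encoded by
membership bitmask; region counts always sum to the union size.

Coverage is `100·|shared ∩ reference|/|reference|`, rounded **half-up**
to 2 decimals via decimal arithmetic (binary-float "round" would give
banker's rounding, which disagrees on values like 96/1155 = 8.3116…).

## Enrichment

One-sided over-representation only: `p = P[X ≥ k]`,
X ~ Hypergeom(N, K, n), computed by `scipy.stats.hypergeom.sf`. The
background defaults to the union of all annotation members and may be
overridden; query genes outside the background are dropped and counted.
Terms overlapping the query by fewer than `min_overlap` genes
(default 3) are omitted. Adjustment is Holm by default (the "Bonferroni
step-down" used by the interactive enrichment tools this replaces), with
Bonferroni and Benjamini–Hochberg available, all via statsmodels.
`associated % = 100·k/K` reports the share of the term present in the
query.

Calibration: because the hypergeometric statistic is discrete, valid
p-values are *super*-uniform (`P[p ≤ x] ≤ x`), not uniform; a two-sided
KS test against U(0,1) rejects for purely combinatorial reasons. The
calibration test therefore applies the one-sided KS test in the
anti-conservative direction, which is the correct type-I check for a
discrete test.

## Synthetic data

The generators produce inputs with the statistical structure the
analysis assumes, at the scale of the reference regime:

- **network** (defaults: 906 nodes, 9647 edges): preferential-attachment
  background over a random arrival order, plus planted Erdős–Rényi
  blocks (defaults: 79, 44 and 59 nodes at densities giving 881, 404 and
  287 within-block edges). The total edge count is adjusted to the
  target exactly. Planted blocks are kept mutually non-adjacent so that
  block membership is a well-defined ground truth for module-recovery
  benchmarks; background edges may still attach blocks to the rest of
  the network. Edge confidences default to Uniform(0.701, 0.999) —
  emulating a network already filtered at > 0.7 — with planted-block
  edges drawn from Uniform(0.72, 0.999) so the standard filter never
  destroys planted structure; both are configurable (e.g.
  Uniform(0, 1) to exercise the filter);
- **gene lists** (defaults: 1155 disease genes, 318 targets, 96 shared):
  disease genes are degree-biased samples (weight degree+1), emulating
  the hub enrichment of literature-curated disease lists; when the
  requested list exceeds the network size the surplus becomes
  off-network identifiers, mirroring disease genes that do not map into
  the PPI network. The target list shares exactly `overlap_count`
  members with the disease list, drawn uniformly from it. Because that
  draw is uniform, hub-level coverage of the synthetic target list is
  near chance (≈|shared|·|hubs|/|disease|) — real compound-target data
  concentrates in hubs, and the generator makes no attempt to emulate
  that concentration;
- **annotations**: uniform random term memberships over the node
  universe; a designated query in which each member of a planted term is
  included with probability `min(1, factor · query_size/N)` — `factor`
  times the base inclusion rate — and the rest filled uniformly.

All generators derive every draw from `numpy.random.default_rng(seed)`
with fixed iteration orders: one seed gives byte-identical artefacts.

### What the benchmarks show — and what they do not

Planted-clique recovery (cliques of ≥ 8 nodes on a background with mean
degree below the MCODE degree cut-off, recovered with Jaccard 1.0 in 20
of 20 seeded replicates) demonstrates algorithmic correctness, not
real-data performance: in a dense disease network the background exceeds
the degree cut-off everywhere and detected complexes are the densest
cores of diffuse modules, not exact planted sets. Likewise the planted
16-gene triple-centrality elite is a constructed identifiability check.

The planted-enrichment benchmark uses pathway-scale terms (30–80
members, 80-gene query, 800-gene background). Power analysis fixes that
choice a priori: with a 5× inclusion rate the expected overlap for a
K-member term is ≈ 0.5·K, while ranking first at Holm-adjusted p < 0.05
over 25 terms needs roughly k ≥ 9 at K = 30 (null mean 3) — satisfied
with > 99% probability at K ≥ 30 but fundamentally out of reach for
terms under ~25 members, where no implementation could pass. Small terms
are exercised by the calibration test instead.

## Problem sizes and numerics

Unit tests run on 80–200-node networks; acceptance checks run the full
pipeline twice at the 906-node default regime (seconds per run) and the
oracle comparisons on graphs of up to 120 nodes, sizes at which the
brute-force oracles are exact and fast. Oracle agreement is asserted to
1e-9 absolute (betweenness) and 1e-9 relative (hypergeometric tails);
worked-example scores are asserted to the 0.01 printed precision.
Degenerate inputs are defined, not special-cased: density of a
zero-or-one-node graph is 0, closeness of an isolated node is 0,
betweenness in components smaller than 3 is 0, cluster score below two
nodes is 0.

## Known limitations

- No live database queries (interaction, disease-association,
  drug-target or annotation); all inputs are files or synthetic.
- Species filtering, tissue-specificity scoring and molecular docking
  are out of scope.
- The enrichment module tests over-representation only; no depletion,
  and no term-grouping/kappa clustering of enriched terms.
- MCODE's fluff post-processing can produce overlapping complexes; the
  default configuration (fluff off) guarantees vertex-disjoint output.
- The scale-free generator matches degree heavy-tailedness and planted
  density, not the evidence-channel composition of real interaction
  confidence scores.
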