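# Methods

This note records the statistical and algorithmic choices in `netpharm`, the
parameters and their defaults, where the implementation substitutes a
documented local statistic for a web service, and the known limits of the
synthetic generator.

## Symbol handling and set algebra

Gene symbols are trimmed and uppercased; tokens with internal whitespace or
that normalize to the empty string are rejected. An optional two-column
alias table maps vendor identifiers to official symbols; unmapped tokens are
*kept* (uppercased) and surfaced through a warning channel rather than
dropped, so set sizes stay conservative and auditable. Per-entity sets union
their per-source lists with per-gene provenance, and Venn decomposition
assigns each gene of the union to exactly one region keyed by the frozenset
of containing labels (2–6 sets; counts therefore sum to the union size).

## Association expansion

The expansion step ranks non-seed genes of a weighted association network by

    score(g) = Σ_{s ∈ seeds, (g,s) ∈ E} w(g,s) / sqrt(deg(g))

and returns the top k (default 20), ties broken lexicographically, zero
scores never returned. The square-root degree penalty damps promiscuous
hubs, the same intuition as the normalized adjacency operator in label
propagation, while staying deterministic and brute-force checkable. This is
a *substitute* for service-based association expansion, whose internal
multi-network weighting is not reproducible offline; only the output
cardinality semantics are preserved.

## PPI filtering

STRING-style TSV edge lists are parsed with score-scale auto-detection
(`milli` iff any score exceeds 1), dedupe-max over duplicate/reversed pairs,
and self-loop removal. The confidence filter keeps edges with weight ≥
threshold (default 0.7; the inclusive reading matches the STRING UI's "high
confidence 0.700"), and node dropping is a separate explicit step, mirroring
the two independent export choices. The filtered network is treated as
unweighted by everything downstream.

## Centralities and the consensus rule

Four local centralities are computed per node: degree; MNC (size of the
largest connected component of the open neighborhood); MCC (Σ over maximal
cliques C containing v of (|C|−1)!, exact big-integer arithmetic, maximal
cliques via Bron–Kerbosch with pivoting, abort above a configurable cap of
10^6 cliques); and EPC (mean size of v's component over 1000 seeded
percolation replicates with per-edge retention 0.5, vectorized through
sparse connected-components). A node is a core target when its value is
*strictly* above the per-algorithm arithmetic mean of all four
simultaneously; means are taken over all nodes of the analyzed (filtered,
isolate-dropped) graph, and the integer-valued comparisons are decided in
exact arithmetic (`value·n > column sum`) so floating-point noise can never
flip a tie at the mean. EPC replicates, retention and seed are
config-exposed and logged.

## MCODE

Vertex weight is k·density of the highest k-core of the closed neighborhood
N[v], zero below the degree cutoff. Complexes grow greedily and
breadth-first from the highest-weight unassigned vertex, admitting
unassigned neighbors with weight ≥ w(seed)·(1 − node_score_cutoff); each
vertex joins at most one complex. Post-processing discards complexes without
a 2-core, then applies the haircut (iterated removal of singly-connected
vertices, i.e. the 2-core); the score, density × size, is computed after
post-processing, and ranking is by score, then size, then seed name.
Defaults: degree cutoff 2, node score cutoff 0.2, haircut on, fluff
unsupported (rejected rather than silently ignored), k-core 2, max depth
100. The 2-core-filter-then-haircut ordering follows the reference
description of the algorithm.

## Over-representation and TF ranking

ORA uses the one-sided hypergeometric tail p = P(X ≥ k) with N the universe
size, n the universe-restricted query, K the term size and k the overlap;
k = 0 terms are retained at p = 1 so the Benjamini–Hochberg family size
equals the library size. The odds ratio is the 2×2 contingency ratio
k(N−K−n+k)/((K−k)(n−k)), +∞ when a denominator cell is zero with k > 0. The
universe defaults to the union of term genes; a fixed background override is
available because web-tool backgrounds are generally not recoverable —
consequently, odds ratios from web tools are not reproduction targets.

The transcription-factor ranking is an explicitly labeled permutation
substitute for motif/track-based NES scores, which cannot be computed
offline: the observed count of query genes in each regulon is z-scored
against ≥100 (default 1000) random same-size queries drawn uniformly from
the universe, ranked by NES descending, then hit count, then name. Ranking
semantics match the motif-based original; absolute NES values do not.

## Pipeline determinism

A single configured seed is fanned out to per-stage sub-seeds through fixed
integer channels of a splittable generator, so EPC and TF randomness are
independent and adding a stage cannot shift another's stream. Every stage
persists its outputs and reads its inputs from persisted artifacts, making
single-stage reruns reproducible; `report.json` is serialized with sorted
keys and no timestamps, and two runs with identical config and seed are
byte-identical.

## Synthetic generator: design and limits

All sampling is integer-indexed over sorted sequences through seeded
generators, so fixtures are bit-identical across platforms. Venn layouts are
*constructed* from exact region counts, not sampled, so set-algebra tests
are sharp. Planted associates receive three high-weight seed links against a
background of at most one weak link, which separates their scores from the
background deterministically (3·0.7/√3 ≈ 1.21 > 0.7). PPI fixtures plant
fully wired high-confidence cliques, optional hub nodes attached to the
three largest cliques, and designated isolates with only sub-threshold
edges; the non-isolate background is a high-confidence spanning tree plus
Erdős–Rényi extras whose high-confidence subgraph is iteratively demoted
until it contains no 2-core. That last constraint is a deliberate deviation
from a bare Erdős–Rényi background: without it, background triangles above
the confidence threshold appear in a seed-dependent fraction of fixtures and
would turn exact module-recovery checks into statistical ones.

Limits: gene symbols are synthetic (`G000001`…), degree distributions are
not scale-free, association weights are uniform rather than
evidence-channel-structured, and library terms are uniform random draws —
the generator is built for sharp recovery testing, not biological realism.
Hub-adjacent planted cliques are absorbed into one module together with
their hubs (the hubs are wired to every clique member by construction), so
module recovery in hub-bearing fixtures is containment, not equality; the
hub-free fixtures used for module-recovery acceptance have no such overlap.

## Verification

Unit and property tests check every operation against independent
brute-force oracles living in `tests/_oracles.py`: subset-enumeration
maximal cliques and neighborhood components, exact 2^m percolation
enumeration with exact variances, rational-arithmetic hypergeometric tails,
and a from-definition Benjamini–Hochberg. The acceptance suite covers the
count identities, oracle equivalence on 200 random graphs, planted-hub and
planted-clique recovery across seeds, ORA exactness for all N ≤ 60 with
null-library type-I calibration, planted-regulon rank stability, and
end-to-end byte determinism. Monte-Carlo assertions use 3·SE bounds with a
single independent-seed retest to confirm or refute marginal exceedances,
which are expected roughly once per ~400 three-sigma checks even for an
unbiased estimator.
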