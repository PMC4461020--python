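# Methods

## Network model

A miRNA–disease association network is a simple undirected bipartite graph:
miRNA and disease identifier sets are disjoint, there is at most one edge
per (miRNA, disease) pair, and each edge carries an integer weight ≥ 1
equal to the number of distinct publications supporting the association.
Identifiers are compared case-insensitively after whitespace trimming and
stored in their first-seen form, so `miR-21` and `MIR-21` are one node.

Edge evidence optionally carries the citations themselves (PubMed id plus a
regulation direction from {up, down, unspecified}). When citations are
present the weight is defined as the number of *distinct* PubMed ids — a
publication reporting both an up- and a down-regulation counts once. When
duplicate edge records are merged, citation-bearing records pool their
distinct ids and recompute the weight; two citation-free records are
treated as disjoint literature batches and their weights add (there is no
way to detect overlap without ids).

## Maximum-weight matching and disease ranking

The prioritization objective is the 0/1 program

maximize Σ w_ij·x_ij subject to Σ_j x_ij ≤ 1 per miRNA i, Σ_i x_ij ≤ 1 per
disease j.

On bipartite graphs the LP relaxation of this program is integral, so any
exact solver is equivalent to solving the LP with simplex and rounding; the
test suite verifies this equivalence with an independent LP solve (HiGHS).
Internally the optimum value is obtained with networkx's exact
blossom-based `max_weight_matching`; the specific optimal matching is then
pinned down deterministically: edges are scanned in sorted
(mirna_id, disease_id) order and an edge is kept whenever an optimal
completion still exists. This returns the maximum-weight matching whose
sorted pair list is lexicographically smallest — ties between co-optimal
matchings are otherwise arbitrary, and downstream results must be
reproducible. Objective arithmetic is exact integer arithmetic throughout.

A separate brute-force oracle enumerates all matchings by recursive
include/exclude over the sorted edge list with the same tie-break. It
refuses graphs above 20 edges by default (the enumeration is exponential in
the worst case); callers that know their instance is small in practice can
raise the guard explicitly.

**Cumulative impact.** For a query set Q of miRNAs, each adjacent disease d
gets c(d) = Σ_{i∈Q} w_id; diseases are ranked by c descending with
lexicographic tie-break.

**Merge rule.** Let t be the minimum cumulative impact over the matched
diseases. The final list is the matched set plus every disease with
c(d) > t, in ranking order. "Higher-ranked" is interpreted as *strictly
greater impact*, not better ordinal position: this keeps the rule stable
under ties with the threshold disease (a disease tied at t is not added).
The rule is idempotent, never removes a matched disease, and never adds a
disease outside the query's sphere of influence. With an empty matched set
the result is empty and flagged degenerate rather than an error, so batch
pipelines can proceed.

The full pipeline restricts the graph to the induced subnetwork of the
queried miRNAs and *all* their adjacent diseases before matching, so the
optimization sees each query miRNA's complete sphere of influence. Unknown
query identifiers are dropped with a logged warning (aborting would make
interactive use painful); only a fully unknown query raises.

## Topology summaries

Density uses the simple-graph convention 2E/(N(N−1)) over all nodes, not a
bipartite-specific denominator. For reference, a network of 468 nodes and
2998 edges has density 0.02743 under this formula; association networks of
this kind are reported in the literature with densities near 0.027, and a
printed value of 0.0273 for that size is not reproducible by any standard
convention (bipartite-normalized density would be far larger) — we report
the standard formula and note the mismatch rather than chase it.

The power-law diagnostic fits a least-squares line to log10 P(k) versus
log10 k over strictly positive degrees with non-zero counts and reports the
negated slope γ and the fit R². This is a *descriptive* statistic used to
confirm a long-tail shape, not a maximum-likelihood tail estimate; degree
distributions in these networks are used qualitatively.

Shortest paths are minimum-hop; among tied paths the lexicographically
smallest node sequence is returned (computed by a greedy walk over the
BFS distance fields from both endpoints), again for determinism.

The disease–disease projection links two diseases when at least one miRNA
regulates both, weighting the edge by the number of shared miRNAs.
Count-1 edges reproduce the unweighted projection exactly; diseases sharing
no miRNA are retained as isolated nodes so node counts match the source
network's disease partition.

## Motif census and significance

Connected induced subgraphs on 3 and 4 nodes are enumerated with the ESU
scheme (grow from each root only through higher-ordered nodes with an
exclusive extension set), so each node set is visited exactly once;
classification is by size, edge count and degree sequence, which separates
every relevant class: 3-path; 4-path (1,1,2,2); 3-star (1,1,1,3); 4-cycle
(2,2,2,2). The network is treated as undirected and node roles (miRNA vs
disease) are ignored for classification — a 3-path is "one miRNA regulating
two diseases" or "two miRNAs regulating one disease" equally. On
non-bipartite inputs (the disease projection) the triangle appears as its
own class and remaining 4-node shapes are bucketed as `other`.

The null model is the standard degree-preserving double edge swap: pick two
edges (a,b), (c,d) with a,c miRNAs and rewire to (a,d), (c,b) iff neither
target edge exists. Every node's degree, bipartiteness and simplicity are
preserved exactly. round(swap_factor × E) attempts are made
(default swap_factor 10); each edge's weight travels with its miRNA slot,
though weights play no role in motif counting. Note that K_{2,2} admits no
legal swap and is returned unchanged.

Per class, `significance` reports the mean and sample standard deviation
(ddof = 1) of counts over an ensemble of independent randomizations
(default 1000), the Z-score (counts − mean)/std — flagged undefined when
std = 0 — the empirical p (fraction of random networks whose count reaches
the real one), and *uniqueness*: the number of pairwise edge-disjoint
occurrences, computed by greedy packing in sorted occurrence order (the
classic tools do not specify their packing order; greedy-sorted is
deterministic). A boolean `significant` flag applies the conventional
thresholds z ≥ 2, p ≤ 0.01, uniqueness ≥ 4 (all configurable) but nothing
is filtered: the criteria are reported, not enforced.

A consequence of exact degree preservation worth knowing: the 3-path count
(Σ_v C(deg v, 2)) and 3-star count (Σ_v C(deg v, 3)) are pure functions of
the degree sequence, so under this null every randomized network has
exactly the real count, the std is 0 and their Z-scores are undefined by
construction. Only the 4-path and 4-cycle counts vary under edge swaps and
can be meaningfully over-represented. Tools that additionally randomize the
degree sequence (or use sparser swap counts) can report positive Z-scores
for the degree-determined classes; this implementation keeps the stricter
null and flags them.

**Motif-based prioritization** restricts the census to the induced
subnetwork of the queried miRNAs plus their adjacent diseases, then orders
diseases by total participation count over a caller-chosen class subset
(default: all four classes; pass only the 4-cycle to count "square" motifs).
Diseases with zero participation are omitted.

## Synthetic networks

`scale_free_bipartite` grows a bipartite preferential-attachment graph:
a seed edge m1–d1, then alternating new miRNA/disease nodes, each attaching
to min(m, opposite-partition size) distinct opposite-partition nodes sampled
with probability proportional to degree + 1. The +1 kernel lets early
degree-0 nodes acquire edges (pure degree-proportional attachment stalls on
the seed). With m = 2 and 250+250 nodes this yields exactly 996 edges and a
long-tail degree distribution (max degree ≥ 5× median in essentially every
seed, fitted γ ≈ 1.9–2.1). Edge weights are geometric with success
probability `weight_p` (default 0.3, mean ≈ 3.3): citation counts are small
positive integers with a long tail. Everything is reproducible from the
seed, byte-for-byte through a CSV round-trip.

What the generator emulates: sparsity, hub-dominated long-tail degrees,
integer citation-like weights. What it does not: real identifier
vocabularies, correlated disease co-annotation, curation biases, or the
empirical degree sequence of any particular database. Tests passing on
synthetic networks therefore validate the algorithms and their invariants,
not biological conclusions about any specific dataset.

`er_bipartite` (independent edges with fixed probability, uniform weights)
supplies degree-homogeneous fixtures for oracle tests.

## Files and interchange

Edge lists are UTF-8 RFC-4180 CSV with columns
`mirna,disease,weight,pubmed_ids,direction`; multi-valued cells use ";" so
commas never collide. When both weight and PubMed ids are given and
disagree, the distinct-id count wins with a logged warning (ids are the
primary data; the weight is derived). Unknown extra columns are preserved
on read and ignored by algorithms. Result CSVs carry
`rank,disease,mirna,weight,pubmed_ids,directions,score,method`, one row per
association of each reported disease with the queried miRNAs, ordered by
rank, disease, miRNA.

The matching model exports as GNU MathProg text: one binary variable per
existing edge, one objective summing weight × variable, one ≤1 constraint
per vertex incident to at least one edge. Identifiers are sanitized to
MathProg-safe names. Solving the exported model with an external LP solver
attains the exact solver's objective (the LP is integral); within this
package the equivalence is exercised through an LP solve in the test suite
rather than by invoking an external solver binary.

## Problem sizes and numerical choices

Randomized verification runs at sizes where the exhaustive oracles are
exact and fast: matching equivalence on 200 graphs of up to 8×8 nodes,
census equivalence on 50 graphs of up to 12 nodes, projection equivalence
on 100 graphs, generator topology over 100 seeds of 500-node networks.
Null-model unit tests use ensembles of 4–20 networks (library default
1000); significance is bit-reproducible from its seed via spawned child
seeds, so ensemble size affects precision only. All scores and objectives
are integers; the only floating-point quantities are densities, ensemble
statistics and the descriptive power-law fit.

## Known limitations

- The brute-force matching oracle and the all-subsets census oracle are
  exponential; they exist for verification, not production use.
- Motif sizes ≥ 5 and directed motifs are out of scope; participation
  counting treats each occurrence's node set once.
- The power-law fit is descriptive; no statistical test of scale-freeness
  is performed.
- Prediction of unobserved miRNA–disease associations is explicitly a
  non-goal: every reported disease is backed by existing edges.
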