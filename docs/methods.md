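# Methods

This note records the modelling and numerical choices behind `netbackbone`:
what each component computes, where the design was genuinely open, and what
the synthetic benchmark does and does not show about real data.

## Graph model and conventions

The universal input is an undirected simple graph with strictly positive,
finite edge weights interpreted as interaction strengths (larger = stronger).
Node labels are opaque strings; **every** deterministic ordering in the
package — spanning-tree scans, greedy planarity scans, the doubly stochastic
edge-adding loop — uses the total order *(criterion, min label, max label)*.
This makes every extraction reproducible independent of insertion order, and
it is the only place label identity matters: on tie-free weights all methods
commute with relabeling (asserted in the tests).

Self-loops are dropped on input (with a warning) rather than rejected: the
surveyed filters are defined on simple graphs, and spanning/planarity
arguments are undefined with loops. Duplicate undirected pairs — including
reversed `(v,u)` rows, the form a directed export produces — are resolved by
an explicit `dedup_policy` (`error` by default, or `mean`/`sum`/`max`); the
policy is the symmetrization rule, so no separate flag exists. Multigraphs,
temporal networks and weight imputation are out of scope.

## Weight → distance maps

Distance-based methods need a strictly decreasing weight→distance map, which
the backbone literature leaves open. Three are provided:

* `inverse` (default): d = 1/w;
* `inverse_minus_one`: d = w_max/w − 1, a proximity-style map in which the
  strongest edge has distance exactly 0 (the one permitted non-positive
  value);
* `max_minus`: d = w_max + w_min − w.

Order-only methods (MSP, PLAM, UMB, PMFG) are invariant to the choice; the
metric backbone, salience and weighted betweenness depend on it, so the map
name is recorded in every backbone's provenance. All maps reverse the weight
order edge-by-edge (property-tested), so "strongest" always means "closest".

## The extractors

**MSP** is Kruskal's scan in decreasing weight; on disconnected input it
returns the per-component maximum spanning forest.

**PMFG** scans edges in decreasing weight and keeps an edge iff the
accumulated subgraph stays planar (networkx's linear-time planarity test);
the scan stops once the planar bound Σ max(0, 3(n_c − 2)) over components is
reached. Note the greedy result need not have exactly 3(n−2) edges for
arbitrary inputs (a maximal planar subgraph can saturate earlier — K₃,₃ is
the classic example); on complete inputs it is a triangulation and the count
is exact, which is what the tests assert.

**PLAM** keeps each node's maximum-weight incident edge, ties to the
lexicographically smallest partner. With distinct weights the result is a
forest, hence transitivity exactly 0.

**HB** combines the h-strength network (largest natural h such that h edges
have weight ≥ h; the comparison uses the raw real weight against the integer
h, no rounding) with the h-bridge network (the same index applied to edge
betweenness divided by the node count N). Betweenness here is the raw
unnormalized pair count with fractional credit among tied shortest paths,
routed by distance sum on the configured map by default; a hop-count variant
is a flag, since "edge betweenness" is ambiguous for weighted graphs. HB is
deliberately **not** scale-invariant (h compares weights to integers) — the
suite asserts a concrete counterexample (triangle {5,4,3} versus ×0.01) —
and it may isolate nodes.

**MB** keeps an edge iff no indirect path has a strictly smaller distance
sum. Floating-point equality uses `d_e ≤ D·(1+1e−9) + 1e−12`; since D ≤ d_e
holds exactly for a direct edge, only roundoff can separate genuinely equal
values, so the tolerance can only re-admit edges, never drop metric ones.
The backbone preserves every pairwise shortest-path distance (tested).

**UMB** keeps an edge iff its distance equals the minimax (bottleneck) path
distance. The minimax distance is realized on the minimum-distance spanning
forest, which under any strictly decreasing map is the maximum-weight
spanning forest built by the *same* tie-broken scan as MSP — this gives an
O(m·depth) implementation and makes MSP ⊆ UMB hold by construction, ties
included. A consequence worth knowing: with all-distinct weights every
non-tree edge is the strict maximum of its tree cycle, so UMB coincides with
MSP exactly; UMB differs from MSP only in the presence of weight ties
(where it is the union of all maximum spanning trees).

**DS** Sinkhorn-balances the weighted adjacency matrix (alternating row and
column normalization, restricted to non-isolated nodes) until every row and
column sum is within `tol = 1e−8` of 1 or `max_iter = 10000` sweeps elapse.
The per-edge score is the mean of the two directed entries — for symmetric
input Sinkhorn preserves symmetry in exact arithmetic; the mean guards
roundoff. A doubly stochastic matrix with the graph's support need not
exist (a path's end rows both put all mass on the middle column; more
generally any tree with ≥ 3 nodes fails the perfect-matching support
condition), so non-convergence is a *reported outcome*, not an exception:
the pipeline excludes the method pairwise for that network and enumerates
the exclusion. On convergence, edges are added in decreasing score until the
kept-edge graph has the same number of connected components over the
original node set as the original network (for connected input: one spanning
component).

**HSS** computes each edge's salience — the fraction of the N per-root
shortest-path trees containing it, where a root's tree is the union of *all*
minimum-sum paths from that root — and keeps edges with salience ≥ 0.9. The
threshold is configurable; 0.9 operationalizes "salience near 1" given the
near-bimodal salience distributions of real networks, whose bimodality this
package does not re-derive. Salience is an exact count divided by N
(verified against per-root brute-force counting); every edge of a connected
tree has salience exactly 1. HSS may isolate nodes.

## Evaluation metrics

* **Similarity**: Jaccard |E₁∩E₂|/|E₁∪E₂| and the asymmetric overlaps
  |E₁∩E₂|/|E₁| and /|E₂|; two empty backbones compare as identical (J = 1 by
  convention, documented because empty extractions occur, e.g. HB on
  all-sub-unit weights). Aggregation across networks reports the mean and
  the **population** standard deviation (denominator N).
* **Point-biserial correlation** between the 0/1 membership vector (over all
  original edges) and each of: weight, degree product k_i·k_j, strength
  product s_i·s_j, betweenness, weighted betweenness. Implemented from the
  (M₁−M₀)/s_n · √(n₁n₀/n²) formula and tested to equal Pearson's r of the
  dichotomous coding to 1e−12. Degenerate cases (backbone = everything /
  nothing, constant property) are reported missing with a reason rather than
  silently zeroed.
* **Global properties** of a backbone: edge, node and weight fractions;
  weight entropy; reachability; number of components; transitivity. Each is
  normalized by the original network's value, except the component count,
  which is reported raw (a count, compared on a log scale). Undefined ratios
  (original value 0) are reported missing.
  - *Weight entropy* is not standardized in the literature; here it is the
    Shannon entropy (natural log) of the weight proportions p_e = w_e/Σw
    over the edge set in question, with a fixed-bin histogram variant behind
    a flag for sensitivity checks. For m equal weights it equals ln m
    exactly.
  - *Reachability* counts connected unordered node pairs over C(|V_original|, 2),
    so methods that drop nodes are penalized — the intended behavior, since
    node isolation is a connectivity failure of the filter.
* **Distribution comparison**: exact two-sample KS statistics between
  backbone and original weight and degree distributions (backbone degrees
  over kept nodes), tested against a double-loop ECDF oracle; methods are
  ranked per network ascending in KS with average-rank ties. Networks with
  fewer than 1000 edges are excluded by default (small backbones make the
  two-sample comparison uninformative); the cutoff is configuration.

## Behavior matrix

Qualitative per-method verdicts (consistent-yes / network-dependent /
consistent-no) are derived from the global-property table with **declared**
thresholds rather than visual inspection: heavy filtering means edge
fraction ≤ 0.25 on ≥ 90 % of networks; a property is consistently preserved
(lost) when its normalized value is ≥ 0.9 (≤ 0.1) on ≥ 90 % of the networks
where it is defined. The thresholds are configuration, echoed into the
output, so verdict provenance is auditable. Theorem-backed cells (forests ⇒
zero transitivity for MSP/PLAM; spanning ⇒ node fraction 1 and a single
component for MSP/MB/UMB/PMFG on connected input) must — and do — hold on
any panel; the remaining cells are empirical and may legitimately differ
from real-corpus results.

## Synthetic panel

The default panel is 24 seeded graphs from four topology families
(Erdős–Rényi, Barabási–Albert, Watts–Strogatz, stochastic block model)
crossed with uniform, log-normal and Pareto weight laws, all with distinct
weights: sizes 10–500, densities ~0.02–0.9, average clustering ~0.03–0.7.
Design choices, made once:

* Average degree is kept ≥ ~8 on nearly every graph, as in real benchmark
  corpora where even sparse networks carry several times more edges than
  nodes; this is what makes spanning-tree methods heavy filters there.
* The largest graphs are the sparsest and the densest are small, keeping the
  full eight-method × four-experiment pipeline at desk scale (about a minute
  per run).
* Five graphs exceed 1000 edges so the distribution experiment runs at its
  default cutoff.
* Seeds derive as `SeedSequence([panel_seed, index])`, so adding a graph
  never perturbs earlier ones; the same seed reproduces every table
  byte-for-byte.

What the panel does **not** emulate: real degree-weight correlations,
community-weight coupling, the bimodal salience structure of empirical
networks, or sizes beyond ~500 nodes. Passing the panel suite therefore
demonstrates algorithmic correctness and the theorem-backed behaviors, not
corpus-level averages (e.g. cross-method overlap percentages observed on
real collections), which depend on the networks used.

## Numerical and degenerate-input choices

* Metric/minimax equality tolerance `(1+1e−9)·D + 1e−12`, see above; the
  same rule is used by the oracles so comparisons are exact set equality.
* Sinkhorn residual is the max absolute deviation of any row/column sum from
  1, evaluated after each full sweep; isolated nodes are excluded from the
  matrix (an all-zero row can never be balanced).
* The distinct-weight jitter reassigns w_i ← w_i + rank_i·δ with δ starting
  at mean(w)·1e−9/m and doubling until uniqueness holds — order-preserving
  and ≤ 1e−6 relative perturbation in practice.
* Graphs with a single node, empty edge sets, or disconnected components are
  legal inputs everywhere; disconnected pair distances are +∞ and spanning
  methods operate per component. DS's stopping rule targets the *original*
  component count, so disconnected inputs terminate correctly.
* Scale-invariance tests multiply weights by exact powers of two (plus ×3
  for order-only methods) so the check isolates genuine scale dependence
  from float roundoff in distance sums.

## Known limitations

* PMFG uses an O(n) planarity test per candidate edge; on dense
  thousand-node networks this is the slowest path (the classic
  implementations share this cost).
* The doubly stochastic filter materializes a dense matrix over non-isolated
  nodes — fine to a few thousand nodes, not for very large graphs.
* Infeasibility of Sinkhorn balancing is detected by iteration cap, not by a
  structural (perfect-matching) pre-check; genuinely infeasible networks pay
  the full `max_iter` cost before being excluded.
* Betweenness is exact, never sampled; statistical filters (disparity-type
  null models etc.) are deliberately out of scope.
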