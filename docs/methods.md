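# Methods

## Problem and model

`ppiscreen` screens a query gene list against a scored interactome fragment
and nominates candidates purely by network topology. The model of the data
is an undirected simple graph over gene symbols: an edge asserts a
supported protein–protein (or functional) interaction, with an optional
confidence score on the STRING combined-score scale (an integer in
[0, 1000]). The analysis makes two structural assumptions that real PPI
networks usually satisfy: the degree distribution is heavy-tailed
(scale-free-like), so a small number of hubs carry most connectivity, and
the recognized query genes form one dominant connected component plus a few
isolated nodes. The screening cascade is meaningful exactly when those
assumptions hold; on a degree-homogeneous graph the "top 10 %" cut is
arbitrary tie-breaking.

## The selection cascade

Let the analysis scope be the main connected component (default) with
`n` nodes.

1. **Hubs** = the `max(1, floor(hub_fraction · n))` highest-degree nodes
   (`hub_fraction` default 0.10).
2. **Bottlenecks** = the top `bottleneck_k` nodes by betweenness
   (default 10 — an absolute count, not a fraction).
3. **Hub-bottlenecks** = hubs ∩ bottlenecks, kept in hub-rank order.
4. **Central nodes** = hub-bottlenecks present in BOTH the top-`crossval_k`
   closeness ranking and the top-`crossval_k` stress ranking.
   `crossval_k` defaults to the hub-set size, making the cross-validation
   exactly as stringent as the hub cut; it is configurable because no
   single convention exists for "top nodes" in this step.

Ties at any cutoff are broken by gene symbol ascending; `expand_ties=True`
instead admits the whole tie group. The symbol tie-break was chosen for
determinism — two runs on the same input always produce byte-identical
output, which a rank-unstable policy cannot guarantee.

Scope defaults to the main component because a fractional hub cut over a
network padded with isolated nodes silently loosens the threshold (10 % of
114 nodes is 11 hubs; 10 % of the 105-node main component is 10).
`scope="whole_network"` is available when the isolated nodes should count.

## Centrality statistics

All four statistics are computed on the unweighted graph — scores never
enter distances — by one BFS-based pass per source node:

* **Degree** `D(v)`: incident-edge count.
* **Betweenness** `BC(v) = Σ_{s<t, s≠v≠t} σ_st(v)/σ_st`, accumulated with
  Brandes' dependency recursion and divided per connected component by
  `(n_c−1)(n_c−2)/2`, so values lie in [0, 1] even on disconnected graphs
  (this mirrors how NetworkAnalyzer-style tools report BC); components of
  size ≤ 2 get 0. `normalized=False` returns raw unordered-pair sums.
* **Closeness** `CC(v) = (n_c−1) / Σ_{u∈component} d(v,u)` — the reciprocal
  of the mean intra-component distance; isolated nodes get 0 by convention
  (harmonic closeness is deliberately not used, so CC is comparable only
  within a component).
* **Stress**: the number of shortest paths, over unordered node pairs, that
  cross `v` as an interior vertex. Computed exactly in integer arithmetic
  by a Brandes-style accumulation: for source `s`, the contribution to `v`
  is `σ_sv · x_s(v)`, where `x_s(v)` counts shortest-path-DAG paths from
  `v` to its descendants; summing over sources counts each unordered pair
  twice, so the total is halved. Each distinct path is counted once;
  `count_ordered=True` doubles the values for parity checks against tools
  that sum over ordered pairs.

Numerical choices: BFS neighbor iteration and the per-source loop are
sorted, fixing the floating-point accumulation order, so betweenness is
bit-reproducible run to run; betweenness uses float arithmetic (verified
against an exact-rational brute-force oracle to 1e−12 on graphs up to 10
nodes); degree and stress are exact integers by construction.

The brute-force oracle (`brute_force_metrics`) enumerates every shortest
path of every pair by predecessor backtracking, scores betweenness with
`fractions.Fraction`, and refuses graphs above 12 nodes, where enumeration
stops being cheap. It shares only the BFS predecessor structure with the
fast path; the path counting and accumulation are entirely independent.

## Ingestion rules

Gene symbols are upper-cased on ingestion and compared literally — no
alias or identifier mapping is attempted (a mixed IL8/CXCL8 list will be
treated as two symbols), and query genes absent from the edge table's node
universe are reported as unrecognized rather than guessed at. Edge tables
are whitespace-separated `nodeA nodeB combined_score` rows with an optional
header (detected by a non-numeric third column); reciprocal duplicate rows
collapse to the maximum score *before* the confidence threshold is applied
(STRING exports are symmetric; max-then-threshold is the deterministic
choice that never drops an edge one direction of which qualifies).
Self-loop rows never produce an edge, but a qualifying self-loop row does
register its endpoint as a node — the edge-table writer exploits this to
round-trip isolated nodes through a format that otherwise cannot express
them. The default confidence cutoff is 400 (STRING's conventional "medium
confidence"); it is configurable because source databases and versions
differ in score calibration.

## Synthetic ground truth

The generator emulates the three structural features the cascade relies on:

* a **scale-free main component** grown by preferential attachment
  (Barabási–Albert-style): a star on `attachment + 1` nodes, then each new
  node attaches to `attachment` distinct existing nodes drawn
  degree-proportionally from a repeated-nodes urn (`attachment` default 2,
  giving the sparse, hub-dominated shape typical of curated PPI fragments
  at medium confidence);
* **planted central nodes**: `n_planted` nodes additionally wired to
  `ceil(planted_coverage · (n_connected − 1))` partners sampled without
  replacement, so a planted node's degree — and in practice its
  betweenness, closeness, and stress — dominates the rankings, giving the
  screening tests a known answer;
* **isolated nodes**: `n_isolated` edge-free nodes appended, emulating
  query genes recognized by the database but without qualifying
  interactions.

Everything is a pure function of the spec's seed (`random.Random`, no
global state). Fixture edges all carry score 999 so any threshold ≤ 999
preserves the generated graph. An Erdős–Rényi generator of matched size
and edge count serves as the null model for heavy-tail contrast checks.

What the generator does **not** emulate: confidence-score heterogeneity,
alias ambiguity, evidence channels, expression values, or the community
structure of real interactomes. Passing tests therefore demonstrate that
the pipeline's logic is correct on networks with the assumed shape — not
that any particular biological network will yield stable candidates.

## Test and experiment sizes

The oracle-equivalence sweep uses several hundred random graphs with 2–10
nodes at edge densities 0.2/0.5/0.8 — the regime where exhaustive path
enumeration is exact and instant while still exercising disconnected,
tied, and multi-path cases. Cascade invariants are property-checked on
random graphs of 5–40 nodes; planted-hub recovery uses 50 replicates of a
100-node, attachment-2 graph with one node wired to half the network, and
the study-shaped pipeline check uses a 105-connected/9-isolated network.
These sizes were chosen so each suite exercises its target behaviour at
full strength while the whole suite stays interactive.

## Known limitations

* Centrality is all-pairs BFS, `O(n·m)` time: comfortable to a few
  thousand nodes, not intended for whole-interactome graphs.
* No statistical test accompanies hub status — the cascade is a ranking
  heuristic, and no permutation null is computed (by design).
* Published absolute centrality values from database-backed analyses are
  generally not reproducible without the exact database version and score
  cutoff, both of which such reports often omit; this package treats such
  values as context and validates its statistics against closed forms and
  exhaustive oracles instead.
* Closeness is per-component; comparing CC across components of different
  sizes is not meaningful.
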