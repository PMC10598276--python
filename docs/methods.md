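# Methods

## Scope and model

`netvuln` analyses how the topology of an undirected simple network
determines its vulnerability to attacks. Throughout, a network is
`G = (V, E)` with `n = |V|` nodes, `m = |E|` edges, adjacency `A`, degrees
`k_i`, and shortest-path distances `d(s, t)`. Connectivity is always gauged
by the size of the largest connected component (LCC).

### Topological indicators

For each network we compute seven indicators:

* **Average shortest path** `ASP = Σ_{s,t} d(s,t) / n(n−1)` over ordered
  pairs. Distances on disconnected graphs are computed within the LCC (this
  is standard for the diameter; we extend it to ASP for consistency and flag
  the restriction in the profile).
* **Degree assortativity** `r`: Pearson correlation of degrees across edges.
  On regular graphs (zero degree variance across edge endpoints) the
  correlation has no value; we raise/flag this explicitly rather than report
  0, because 0 ("neutral mixing") is a substantive claim.
* **Density** `d = 2m / n(n−1)`.
* **Diameter**: maximum shortest-path distance within the LCC.
* **Transitivity** `T = 3 · #triangles / #triads` (0 when no triads, flagged).
* **Global efficiency** `e = mean over ordered pairs of 1/d(i,j)`, with 0 for
  disconnected pairs; `e = 1` exactly on complete graphs, `0` on edgeless ones.
* **Modularity** `M = 1/2m · Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)` for a
  detected partition.

Community detection defaults to classic greedy agglomerative
(Clauset–Newman–Moore) modularity maximisation, executed via igraph's
`community_fastgreedy` on a deterministically ordered copy of the graph
(nodes sorted by identifier, edges lexicographic), with the dendrogram cut
at the modularity peak. We chose this variant deliberately: it reproduces
the standard reference value `M ≈ 0.381` on the Zachary karate club, whereas
newer greedy implementations follow a different (higher-scoring) merge path
to `M ≈ 0.41`. Greedy agglomeration is a heuristic: on paths of six or more
nodes it provably stops short of the exhaustive-partition optimum, which our
oracle tests document. Seeded Louvain is available via `method="louvain"`.

### Robustness indices

For a full removal sequence of nodes (edges), `S(q)` is the fraction of
*original* nodes inside the LCC after each single removal, and

    R_n = (1/|V|) Σ_q S(q),        R_e = (1/|E|) Σ_p S(p).

Normalising by the original node count keeps `S` comparable across steps and
makes `R ∈ [0, 1]`. The curves are computed with a reverse union-find sweep
(elements re-added from the back of the removal order), which is
`O((n+m) α)` per curve; tests verify it against naive per-step recomputation.

### Attack models

Node attacks rank nodes by one criterion — random (seeded shuffle), degree,
betweenness (unnormalised pair counts; the ranking is what matters and it is
invariant to normalisation), closeness (raw reciprocal distance sum,
computed within the node's component so scores stay finite), or local
clustering — and remove the top `round(fraction · n)` nodes (at least one
when the fraction is positive; rounding is half-away-from-zero so that 10%
of 34 nodes is 3).

Edge scores for growth/depletion are endpoint products
`w^m_{x,y} = C_m(x) · C_m(y)`, plus inverse preferential attachment
`iPA = 1/(k_x k_y)` (expressed as a score so that descending order uniformly
realises "low-degree-product edges first") and seeded-uniform random scores.
Centralities are **static**: computed once on the original network, never
recalculated during batched removal. Ties are broken everywhere by the
ascending string form of the identifiers (lexicographic pairs for edges), so
every ranking, batching and trajectory is bit-reproducible.

After a fractional node attack, we also measure `R_n`/`R_e` of the attacked
network. The removal order used inside those curves is the same static
criterion ranking restricted to the surviving nodes/edges — consistent with
the static-centrality convention above.

### Growth and depletion trajectories

Scored edges are split into `n_batches` (default 100) contiguous
descending-score groups whose sizes differ by at most one (a remainder of
`r` puts one extra edge into each of the first `r` groups; empty groups are
dropped). Growth starts from the edgeless graph on the original node set
and restores batches in order, ending exactly at the original network;
depletion runs the reverse. The trajectory records LCC size, component
count, and (optionally — it is the one expensive column) LCC diameter after
every batch.

The label statistic for the attribution stage, `links_to_half_lcc`, is
deliberately defined at single-edge granularity and is therefore invariant
to batching: it is the smallest number of individual removals (descending
score) after which the LCC holds at most half of the *original LCC's* node
count (using the LCC rather than `n` as the baseline makes disconnected
inputs behave sensibly). A direction flag allows ascending-order removal;
the default follows attack semantics (highest scores first).

### Attribution (PLS-DA)

Across an ensemble of networks, each indicator column is discretised to
quartile codes: 1.0 above the third quartile, 0.75 above the median, 0.5
above the first quartile, 0.25 otherwise, with strictly-greater comparisons
at each boundary and linear-interpolation quartiles (the common statistical
convention). Missing indicator values (e.g. undefined assortativity) are
excluded from the quartile fit and receive the lowest code. Labels are a
median split of the removal counts: 0 strictly below the median (fragments
easily), 1 otherwise. Label counts use raw removals by default; since raw
counts conflate size with robustness across heterogeneous ensembles, the
ensemble generator matches sizes instead (below).

The coefficients come from single-response PLS regression (NIPALS, via
scikit-learn) of the centred labels on centred, unit-variance-scaled codes,
back-projected to the feature space. PLS is used instead of ordinary least
squares because the indicators are strongly collinear. Two latent
components are the default — standard for a 7-column problem and stable in
our tests; at full rank the coefficients provably equal the least-squares
solution and with one component they are proportional to the standardised
covariances, and both identities are enforced as tests. Zero-variance
columns are dropped with a warning and report coefficient 0. We keep all
seven indicators (including efficiency) as features; one standalone analysis
is run per failure model (DPA, BPA, CPA, CcPA, RND, iPA), yielding a
coefficient table with one column per model.

Supplementary to the coefficients, `indicator_robustness_correlation`
reports Spearman rank correlations (with two-sided p-values, no
thresholding) of each raw indicator against `R_n` and `R_e`.

### Repair

The attack-and-reconstruction experiment iterates rounds of: remove the
`k_remove` highest edge-weight links (endpoint centrality products
**recomputed on the current graph** — unlike the static trajectory stage,
the repair loop is adaptive by construction), then greedily restore
`k_restore` absent pairs, re-scoring candidates after every addition.
Restoration scenarios: push assortativity toward zero (maximise
`1/max(|r(G+e)|, ε)` with `ε = 1e−9`), make it disassortative (minimise
`r(G+e)`), two combined assortativity/modularity ratios on
min–max-normalised candidate scores, and a seeded random baseline.
Candidates whose post-addition assortativity is undefined are skipped.
Assortativity of `G+e` is evaluated incrementally from sufficient statistics
(`Σk²`, `Σk³`, edge degree-product sum) in `O(deg)` per candidate; tests
verify the increment against full recomputation.

The log records both fragmentation events — edges remaining when the
component count first exceeds 1, and when the LCC first reaches half the
original size. Events are observed at the **end of a full round**: a
fragmentation that the same round's restorations heal does not count,
because the question is whether the *repaired* network stays whole. The
iterated-rounds design (rather than a single remove/restore shot) is forced
by the event definitions, which require progressive loss; a `one_shot` mode
is available.

## Synthetic data

The generators provide everything the analysis assumes, offline:

* `gen_ba(n, m_attach, seed)`: preferential attachment from `m_attach`
  initial nodes; edge count is exactly `(n − m_attach) · m_attach`
  (e.g. 1491 for n=500, m=3 — the one property of this generator treated as
  deterministic; degree-dependent quantities vary by seed).
* `gen_planted_modular(n, k, p_in, p_out, seed)`: equal blocks (last absorbs
  the remainder) with independent within/between coin-flip edges; returns
  the planted partition. With `p_in = 1, p_out = 0` and two blocks the
  planted partition scores exactly `M = 0.5`; with `p_in = p_out` the
  planted split carries no signal and its mean modularity sits at the
  finite-size pair-count expectation `−1/(2(n−1))`.
* `rewire_to_assortativity`: degree-preserving double-edge swaps accepted
  only when they move `r` toward the target (Xulvi-Brunet–Sokolov-style
  accept/reject), with `O(1)` incremental score updates; stops within 0.02
  of the target or after `max_swaps` proposals (default `20 m`), returning a
  best-effort graph with a warning when the target is unreachable for the
  degree sequence.

### The fragile/robust ensemble

`vulnerability_ensemble` builds the labelled contrast the attribution stage
is supposed to detect. Fragile-profile networks are chains of four
hub-dominated communities: each block is a 24-node preferential-attachment
graph (`m_attach = 4`) rewired toward `r = −0.4` *within the block*, and
consecutive blocks are joined by a single bridge whose endpoints are drawn
with probability inversely proportional to degree. This realises, in one
construction, the profile the analysis associates with vulnerability:
strong community structure (detected `M ≈ 0.7`), local hubs wired to
low-degree nodes (`r ≈ −0.35`), and inter-community connectivity carried by
a few peripheral links. Robust-profile partners are planted graphs with
`p_in = p_out` matched to the fragile edge count — no community structure,
`r ≈ 0`, and identical `n`, so the halves differ in modularity and
assortativity but not in size (edge counts match within a few percent).

Per-block rewiring (rather than global) is deliberate: global
degree-preserving swaps toward negative `r` destroy both the community
structure and the bridge sparsity they are supposed to coexist with.

What the ensemble does *not* emulate: the heavy-tailed size range, weighted
or directed interactions, and the domain diversity of real network corpora.
Passing sign-recovery tests on this ensemble shows that the pipeline
correctly attributes an engineered modularity/assortativity contrast — not
that those two indicators dominate in any particular real-world corpus.

## Problem sizes and numerical choices

Study-scale defaults used by the tests and the acceptance script: ensembles
of 24 networks of 96 nodes (5 seeds), scale-free graphs of 500 nodes with
1491 edges (10 seeds for attack ordering), a complete 30-node network for
repair (10 seeds, remove 10 / restore 5), and 100 batches for trajectories.
Brute-force oracles (exhaustive partitions, per-step LCC recomputation,
exhaustive candidate scoring) run on graphs of at most 8–12 nodes, where
enumeration is exact and fast.

Degenerate inputs are handled by explicit flags or errors, never silent
zeros: singleton-LCC distances report 0 with a flag, zero-triad transitivity
reports 0 with a flag, undefined assortativity is missing-with-flag in
profiles and an error when requested directly, edgeless graphs refuse
community detection, and constant label vectors abort the discriminant
analysis (a median split of identical counts is meaningless).

## Known limitations

* Greedy modularity is heuristic (see above); Louvain, also heuristic, may
  find different partitions.
* Betweenness-based stages dominate runtime on large graphs
  (`O(nm)` per evaluation); the repair loop recomputes centralities each
  round and is intended for small demonstration networks.
* The PLS coefficient *magnitudes* depend on the collinearity structure of
  the coded features; only their signs and relative sizes are interpreted.
* Indicator profiles treat networks as unweighted, undirected simple
  graphs; directed or weighted inputs are symmetrised/flattened on load.
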