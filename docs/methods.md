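# Methods

## Problem setting

Clinical trials profile transcriptomes of many patients at very few visits
(typically 3–4), with missing visits and heterogeneous response dynamics.
Global pseudotime orderings built from visit times alone cannot separate
fast from slow responders, and single-cell trajectory tools assume far more
samples than such cohorts provide. cohortflow treats each patient's pair of
consecutive visits as a *commodity* — a unit of demand that must travel from
the earlier sample to the later one through the cohort's expression
neighborhood graph — and infers each patient's disease path as the route the
commodity takes. Because routes may pass through *other patients'* samples,
a patient whose intermediate disease state was never sampled still gets a
smooth, fully resolved trajectory. Aggregating all routed paths over cluster
states yields a state-transition diagram; its highest-probability walks are
candidate disease subtypes (endotypes).

## Preprocessing

Count matrices are filtered to genes with CPM strictly above 0.25 in at
least 1% of samples (strict inequality; CPM denominators are the library
sizes of the input matrix, which makes the filter idempotent). Duplicate
gene identifiers are resolved by keeping the row with the highest arithmetic
mean (ties: first occurrence). Between-sample scaling uses trimmed mean of
M-values (TMM): the reference sample is the one whose 0.75-quantile of
count/library-size is closest to the cohort mean; M and A values are doubly
rank-trimmed (30% / 5%) and combined with inverse delta-method
(precision) weights; factors are renormalized to zero log-mean. The
implementation reproduces edgeR's `calcNormFactors(method="TMM")` to six
decimals on count matrices with DE genes. Pre-normalized inputs (e.g. RMA
microarray intensities) skip filtering and TMM; only duplicate resolution
applies. Upstream corrections performed by external tools (GC-content
normalization, batch correction) are accepted as an already-corrected input
matrix.

## Embedding, graph, states

Samples are embedded by PCA (default `d = min(50, n_samples − 1)`
components) of the per-gene-centered, optionally log1p-transformed
normalized matrix. The sign of each component is fixed so its
largest-magnitude loading is positive, making the embedding reproducible
across BLAS builds. The connectivity graph is the UMAP-style fuzzy
simplicial set over the embedding: exact Euclidean kNN per sample;
membership `w(u,v) = exp(−max(0, d(u,v) − ρ_u)/σ_u)` with `ρ_u` the
nearest-neighbor distance and `σ_u` bisected (64 iterations, tolerance
1e-5) so memberships sum to `log2(k)`; symmetrization by the probabilistic
t-conorm `W = A + Aᵀ − A∘Aᵀ`. Disease states are Leiden communities
(RB-configuration modularity, seeded, weights = fuzzy memberships).

The neighbor count `k` is the one genuinely dataset-dependent knob: too few
neighbors fragment the graph into islands no flow can cross, too many blur
community structure. When `n_neighbors` is not set, the pipeline scans the
ladder 15, 20, 25, 30, 40, 50, 60 and takes the smallest value whose graph
is connected — the criterion one would otherwise apply by hand per dataset,
made algorithmic.

## Multi-commodity flow

The undirected connectivity edges are expanded into two opposite arcs with
cost equal to the Euclidean distance between the endpoints' PCA embeddings.
Each patient with T observed visits contributes T−1 commodities
(consecutive-visit pairs, demand D = 1); single-visit patients contribute
none. The fractional LP

    minimize   U = Σ_(u,v) c(u,v) Σ_i f_i(u,v)
    subject to Σ_i f_i(u,v) ≤ C                 for every arc (u,v)
               net flow of commodity i = +1 / −1 / 0 at source/sink/other
               Σ_i Σ_u f_i(u,w) ≤ N             for every node w (optional)
               0 ≤ f_i(u,v) ≤ 1

is assembled sparsely and solved with HiGHS (dual simplex, deterministic,
single-threaded, via `scipy.optimize.linprog`). The node constraint counts
*all* inbound flow, including flow terminating at w; since a sample is the
sink of at most one commodity, any N ≥ 1 keeps sink nodes feasible. The
integer version of this problem is NP-complete; the LP relaxation is solved
instead and integrality is recovered during path extraction.

Two devices keep the LP small and well-posed:

- **Hop corridors.** With a hop limit ℓ, each commodity's variables are
  restricted to arcs (u,v) with `hops(s,u) + 1 + hops(v,t) ≤ ℓ` (BFS hop
  distances) — exactly the arcs lying on some s→t walk of at most ℓ hops.
  Commodities with no s→t path inside the corridor are dropped and reported
  (count and fraction logged). ℓ at or above the graph diameter provably
  leaves the optimum unchanged.
- **Capacity escalation.** With many commodities and a tight C the LP can be
  infeasible (e.g. a single bridge arc between two states cannot carry all
  the commodities that must cross it). `solve_flow` reports infeasibility as
  a status plus a suggestion to raise C; `run_pipeline` doubles C (capped at
  the number of commodities, where the arc constraint is vacuous and
  feasibility of reachable commodities is guaranteed) and logs each step.
  Raising C until the instance becomes feasible is the natural response to
  congestion; the escalation is always logged, never silent. Set
  `max_edge_capacity` equal to `edge_capacity` to forbid it.

### Path extraction

The LP may return fractional flows. Per commodity, arcs carrying flow at or
above `flow_threshold` (default 0.5) are followed from the source; if they
do not form a single source-to-sink path, the commodity's flow is
decomposed by repeatedly stripping the maximum-bottleneck s→t path (widest
path by modified Dijkstra; ties broken on node index), and the
highest-weight path is returned, ties preferring the lexicographically
smaller node sequence. Residual demand above 1e-6 after decomposition
raises an error, as it indicates a solver-tolerance problem rather than a
modeling one.

## State diagram and trajectory ranking

Each extracted path is mapped to its samples' cluster states and
consecutive duplicates are collapsed (so the count matrix has a zero
diagonal and no self-loops). All consecutive state pairs are tallied into
transition counts; rows are normalized to probabilities, with zero-count
rows flagged absorbing and excluded from walk continuation (no
pseudocounts). Initial and final state probabilities are the empirical
distributions of each patient's first and last *observed* visit — the same
rule regardless of missing visits.

A trajectory of L transitions is scored
`init[s₀] · Π P[s_k, s_{k+1}] · final[s_L]`. Because state spaces are small
(≤ ~12), the top-k trajectories are found by exact enumeration over
repeat-free sequences (deterministic, strictly better than sampled walks);
a seeded sampling fallback exists for state spaces beyond the enumeration
budget of 10⁷ sequences. Trajectories that are contiguous subsequences of a
higher-ranked one are annotated as such, never filtered. For display, the
diagram can be pruned per state to the fewest top outgoing edges holding at
least a target share (default 50%) of the outgoing weight, re-normalized
over the kept edges. Note that pruning with re-normalization is not
idempotent when a state keeps several near-tied edges; the kept edge set
can only shrink under re-pruning.

## Gene ranking

Genes are ranked between two sample groups by
`score = −log10(adj p) · log2(FC)`: a two-sided two-sample
Kolmogorov–Smirnov test per gene (exact for small groups via scipy),
Benjamini–Hochberg adjustment across genes, and fold change computed on
pseudocounted (default +1) linear normalized group means. Adjusted p-values
are floored at 1e-300 before the log. The ranked list is exported as a
header-less two-column tab-separated file for prerank-style enrichment
tools; running the enrichment itself is outside this package.

## Synthetic cohorts

The generator plants a small latent-state geometry and trajectories through
it, then emulates the sampling regime of short clinical series:

- **Geometry.** Default: six states in 2-D latent space — a four-state
  chain with two branch states forking symmetrically off its end, centered
  at the origin, consecutive centers `center_separation` (default 4.0)
  apart with latent noise SD 0.5, i.e. separation = 8 noise SDs. Centering
  at the origin matters: the expression map is
  `softplus(latent · loading) · scale` with a fixed random 2→n_genes linear
  map, and an uncentered chain pushes its far end into the softplus/log
  saturation regime where downstream log-scale distances collapse and
  adjacent states merge.
- **Endotypes.** Default two equally likely 5-state sequences 0-1-2-3-4 and
  0-1-2-3-5: a shared disease course with divergent outcomes, the
  archetypal endotype structure.
- **Visits.** Each patient observes 3 of the 5 trajectory positions (first,
  last, one random middle position), so intermediate states are routinely
  skipped and recovery forces the flow to route through other patients'
  samples — the method's core use case. Optional independent per-visit
  dropout; patients left with fewer than two visits are redrawn.
- **Scale.** 60 patients, 150 genes, count-like magnitudes. Everything is
  deterministic given the `CohortSpec` seed.

What the generator does **not** emulate: negative-binomial count dispersion,
batch effects, library-size artifacts beyond what Poisson-free scaling
produces, or biologically structured gene modules. Passing recovery tests
therefore demonstrates the inferential machinery (clustering, routing,
aggregation, ranking) under realistic *sampling* conditions, not robustness
to realistic *noise* models.

Recovery is scored as the fraction of planted endotype sequences appearing
exactly (after collapse) among the top-k inferred trajectories, maximized
over injective relabelings of states, since cluster labels are arbitrary.

## Reference study conditions

The end-to-end evaluation uses the generator defaults above with the
pipeline configured as: automatic neighbor selection, Leiden resolution 0.3
(the planted states are few and well separated; default 1.0 over-splits
dense clusters), hop limit ℓ = 6, edge capacity starting at C = 1 with
escalation enabled, node capacity unset, walk length 4, top-2 trajectories,
20 seeds. On one CPU a single seed runs in roughly 10 s, dominated by the
LP.

## Numerical choices

- LP tolerances: HiGHS defaults; reported flows are clipped to [0, 1] and
  values below 1e-9 dropped. Constraint residuals are verified to 1e-6.
- Smooth-kNN bisection: 64 iterations, tolerance 1e-5 on the membership
  sum; σ floored at 1e-12 (duplicate points are allowed, ρ may be 0).
- Ties: dedup keeps first occurrence; path extraction and trajectory
  ranking break ties lexicographically; pruning breaks weight ties by state
  index. All tie rules are deterministic by construction.
- Seeds: one master seed; per-stage seeds are derived by hashing
  `"{seed}:{stage}"` (SHA-256, reduced mod 2³¹).

## Known limitations

- The LP scales as (commodities × corridor arcs); cohorts beyond a few
  hundred samples need the hop limit, and thousands of samples would need a
  decomposition approach out of scope here.
- Exact-sequence recovery scoring is strict: a single merged or split
  cluster fails a whole endotype even when the route is otherwise correct.
- Demand values other than D = 1 are accepted but unexercised.
- Initial/final probabilities from first/last observed visits are biased
  when missingness correlates with disease state.
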