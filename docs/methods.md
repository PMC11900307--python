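# Methods

## The model

`herbnet` treats herb–disease association as similarity of network
influence. The carrier is a heterogeneous "multiscale" graph with protein
nodes and biological-function nodes and three edge layers: undirected
protein–protein physical interactions (pp), undirected protein–function
annotations (pf), and a directed function hierarchy stored child → parent
(ff). Node classes are disjoint and validated at load time; hierarchy
edges between a protein and a function, or reciprocal child/parent pairs,
are rejected or collapsed with a warning.

### Biased random walk with restart

A walker at node *u* teleports back to the seed distribution `s` with
probability `r`, otherwise steps to neighbor *v* with probability
proportional to the weight of the class transition u→v. Five weights
parameterize the bias:

| weight | transition | default |
|---|---|---|
| `w_pp` | protein → protein | 1.0 |
| `w_pf` | protein → function | 1.0 |
| `w_fp` | function → protein | 1.0 |
| `w_f_up` | function → parent function | 1.0 |
| `w_f_down` | function → child function | 1.0 |

with `r = 0.5` by default. The defaults are deliberately neutral: every
contract in the test suite (fixed-point residual, Monte-Carlo agreement,
seed-mass monotonicity, permutation equivariance) holds across the
parameter space, and no downstream conclusion depends on a particular
tuning. Hierarchy traversal is direction-aware — up and down moves carry
separate weights — with equal defaults, since nothing in the model forces
an asymmetry; both are exposed for users who want one. No hyperparameter
optimization is attempted (out of scope).

The diffusion profile is the fixed point of

```
p = r·s + (1 − r)·(Tᵀp + m_dangling·s)
```

found by power iteration from `p₀ = s`, where `T` is the row-stochastic
transition matrix and the mass at dangling nodes (isolated nodes with no
neighbors) restarts — this guarantees a proper stationary distribution for
any input graph. Convergence is declared when the L1 change drops below
`tol = 1e-6` (cap `max_iter = 500`; exceeded → error carrying the last
residual). Since `r ≥ 0.5` contracts the iteration by at least ½ per
step, convergence is fast and the residual bound `‖p − rhs‖₁ < 10·tol`
is comfortably met. After normalization, entries below 1e-12 are clamped
to zero so serialized profiles are stable; the clamped mass is far below
the 1e-9 sum tolerance. A profile's "top-k" nodes are its k
highest-probability nodes excluding its own seeds (the list should name
*influenced* nodes, not inputs — configurable), ties broken by node ID;
nodes the walk never visits (probability exactly 0) never appear.

An independent Monte-Carlo oracle (`mc_profile`) simulates the walk
literally — restart with probability r, else one categorical neighbor
draw — for a given number of steps and RNG seed, and is compared with the
power-iteration solution in the tests (L1 ≤ 0.02 at 10⁶ steps on ≤30-node
networks) and in `scripts/acceptance.py`. The two routes share no code
beyond the transition distribution itself.

### Ranking statistics

Herb seed sets are the union of all on-network targets of the herb's
compounds with uniform restart weights. The union — not a top-50
truncation — is the default because per-herb target sets naturally vary
in size; the capped variant (targets ranked by how many of the herb's
compounds hit them, ties by gene ID) remains available via
`overlap_from_top_n`, and pathway counts / `top_targets` are exposed on
their own. Per-compound weighting of the restart mass is available but
off by default.

The correlation score is Pearson's r (Spearman optional) between two
profiles over the full node vector, proteins and functions together.
Overlap statistics use the hypergeometric upper tail P(X ≥ k) computed in
log space (`scipy.stats.hypergeom.logsf`), with fold enrichment
(k/n)/(K/N). The universe N defaults to the number of network proteins,
and K to the on-network disease genes; both are explicit inputs. The
significance flag is `p < alpha` (alpha = 1 disables the flag, since
p = 1 exactly when k = 0); flagged-insignificant herbs stay in the
ranking rather than being dropped. Ties in correlation break by entity
ID, so rankings are deterministic and input-order invariant. Raw overlap
p-values are reported without multiple-testing correction across herbs;
ORA across gene-set terms, by contrast, is BH-adjusted.

### Over-representation analysis

Per term: k = |query ∩ term|, raw p from the same enumeration-validated
hypergeometric tail, BH adjustment across the library's tested terms,
z-score (k − E[k])/sd(k) under the exact hypergeometric null, and the
combined ranking score −ln(p_raw)·z (a flag switches the combined score
to adjusted p). The exact-null z-score is a deterministic, reproducible
background; rank-based backgrounds that depend on precomputed random-list
tables are intentionally not emulated. An optional term blocklist filters
terms by ID/description substring (e.g. disease-named terms).

### Mechanism subnetworks

For a compound–disease pair, candidates = top-k(compound) ∪
top-k(disease) ∪ compound targets ∪ on-network disease genes, with
k = 20 by default — large enough to capture the bulk of high-visitation
nodes at the network sizes used here. Edges are the induced multiscale
edges plus anchor edges compound→target and disease→gene. "Unlinked"
compound targets are excluded; linked means directly adjacent in the
multiscale network to any disease-side or top-k node (a ≤2-hop variant
sits behind `two_hop_linkage`). Adjacency is the minimal, deterministic
reading; because the reference set is never itself pruned, the removal
fixpoint is unique and order-independent (verified under randomized
processing orders). The top-ranked node of each profile is flagged
critical. Exports: GraphML (lossless round-trip), Cytoscape JSON, TSV
edge list. All top-k nodes are exported with their profile ranks; no
secondary display filter is applied.

### Transcriptome stage

DEG thresholds follow the printed inequalities exactly: |log2FC| ≥ 1.0
(boundary in) and adjusted p < 0.05 (boundary out). Connectivity-map
similarity scores are consumed from a table and screened at score ≥ 80
(inclusive); computing such scores is out of scope. DEG enrichment
delegates to the ORA machinery, jointly over up ∪ down by default with a
split mode available.

## The synthetic generator

The generator exists so the whole pipeline is testable without external
data, and its defaults define the benchmark conditions:

* **pp layer**: connected Barabási–Albert graph, 200 proteins, attachment
  3 — heavy-tailed degrees like real interactomes; an Erdős–Rényi option
  (degree-matched, components stitched) for ablation.
* **functions**: 40 nodes on 3 levels, each non-top function wired to 1–2
  parents; per-protein annotations Poisson(1.0).
* **disease module**: 15 proteins grown connected by seeded
  random-frontier BFS, internal wiring densified (missing internal edges
  added with probability 0.3).
* **catalog**: 20 herbs × 5 compounds × 4 targets. One planted herb draws
  each target "proximally" with probability p_in = 0.8; decoys with
  p_bg = 0.05; otherwise uniform. A proximal draw picks a module gene
  uniformly and then stays on it or steps to one of *its* pp neighbors
  (50/50). This per-gene step matters: pooling the whole one-hop
  neighborhood uniformly would, on a scale-free graph whose hubs border
  everything, cover 30–60 % of all proteins and dissolve the planted
  signal; the per-gene construction keeps proximal mass proportional to
  module adjacency. With it, the planted herb ranks first in ≥ 90 % of 50
  seeds, and the negative control p_in = p_bg leaves its median rank in
  the middle half of [1, 20].
* **DEG table**: 1000 genes, 50 spiked at |log2FC| = 2.0 + |N(0, 0.3)|
  with padj ~ U(0, 0.005); nulls log2FC ~ N(0, 0.3), padj ~ U(0, 1).
  Under the default thresholds this yields ≥ 95 % spike sensitivity and a
  near-zero false-positive rate (a null needs both padj < 0.05 and
  |log2FC| ≥ 1, jointly ~4·10⁻⁵).

All randomness flows from one config seed through named substreams
(network / disease / catalog / deg), so changing, say, DEG sizes never
perturbs the network. Problem sizes (200-protein benchmark, ≤30-node
oracle networks, 10⁶-step walks) were chosen so the full suite and the
acceptance script each run in well under a minute on one CPU while
keeping Monte-Carlo error an order of magnitude inside its tolerance.

### What the generator does not emulate

Real interactome scale (tens of thousands of proteins), literature and
study bias in compound–target coverage, correlated annotation structure
(real GO terms overlap hierarchically), compound chemistry, and noisy or
conflicting disease-gene evidence. Passing the planted-herb benchmark
therefore shows the method recovers a graph-proximal signal under its own
assumptions — not that any particular real herb is effective.

## Numerical and design notes

* All identifiers are opaque strings; ID harmonization is a user-supplied
  two-column mapping applied at load time — no live mapping services.
* TSV dialect: tab-separated, `#` comments skipped, first row dropped iff
  its first cell matches a known header-name set.
* Deterministic tie-breaks everywhere (gene/entity/node ID ascending), so
  identical config + seed reproduce byte-identical output files; every
  CLI run writes a manifest with a config hash and input checksums.
* TSV output rounds to 4 significant digits; JSON keeps full precision;
  profile TSVs serialize floats with `repr` and round-trip exactly.
* Degenerate inputs fail loudly: zero-variance profiles, empty seed sets
  after network intersection, all-zero transition weights at a populated
  neighborhood ("walker trapped"), inconsistent hypergeometric counts,
  non-convergence.

## Known limitations

Single-threaded dense-ish linear algebra — fine to ~10⁵ nodes, not tuned
for the full public interactome with function layers at GO scale; no
hyperparameter search for r and the bias weights; overlap p-values across
herbs are uncorrected by design; the ORA z-score background is the exact
hypergeometric null, so combined scores are not numerically comparable to
tools using randomization-based backgrounds.
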