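# Methods

This note documents the model, the numerical choices, and the design
decisions behind `metamod`, together with what the synthetic benchmark
does and does not demonstrate.

## Model and assumptions

The pipeline assumes (i) each network feature (EC or metabolite) either
is or is not disease-associated (DA), with its p-value informative about
that state, and (ii) DA features connected by short paths of other DA
features belong to the same functional module. It makes no use of
reaction directionality, stoichiometry, or sample-level data: the inputs
are a bipartite edge list and one p-value table per omic, so any upstream
differential-abundance method can be used, including a different one per
omic. The two omics' p-value distributions are modelled independently.

**Beta-uniform mixture.** Within one omic, p-values are modelled as
f(x | a, λ) = λ + (1 − λ)·a·x^(a−1), a uniform noise component of weight
λ plus a Beta(a, 1) signal component, both parameters in (0, 1). The
model is misspecified in the usual ways (true alternatives are not
exactly Beta(a, 1); p-values from discrete tests are not uniform under
the null), but it provides a convenient closed-form FDR threshold and a
sampling distribution for imputation. The anchor threshold τ solves the
Pounds–Morris identity FDR(t) = π·t/F(t) = q at q = 0.1, with
π = λ + (1 − λ)a the upper bound on the noise proportion and F the
mixture CDF, giving τ = ((π − qλ)/(q(1 − λ)))^(1/(a−1)). The closed form
is verified against a Brent root of the identity at every call
(tolerance 1e-9; observed agreement ~1e-16).

## Tunable parameters

| parameter | default | meaning and rationale |
|---|---|---|
| `fdr_level` | 0.1 | FDR at which τ defines anchors. |
| `k` | 5 | connection requires a DA path of < k edges. See below. |
| `n_iter` | 1000 | Monte-Carlo iterations for M; SE of an entry near 0.2 is ≈ 0.013. |
| `cut` | 0.8 | dendrogram cut; see cut semantics below. |
| `mode` | `one_minus_p` | DA probability of a node with p-value p; see below. |
| `min_anchors` | 2 | a module is *valid* (testable) with at least this many anchors. |
| `B` | 100 | score shuffles for the permutation test; p_perm = (r+1)/(B+1). |
| `p_floor` | 1e-10 | zero p-values are clamped here (the Beta(a,1) density diverges at 0). |

**Path bound k.** In a bipartite reaction–compound graph, distances
between features of the same class are even: two enzymes sharing a
compound are at distance 2, two enzymes separated by one intermediate
reaction at distance 4. The default k = 5 ("< 5 edges", i.e. up to 4) is
the smallest bound that connects enzyme pairs one reaction apart and
metabolite pairs two conversion steps apart, which matches the intuitive
radius of a local pathway neighbourhood. A sensitivity scan on the
planted-module benchmark (k ∈ {3, 4, 5, 6}) shows recovery is poor at
k = 3 — where only features of the same single reaction can ever
cluster — rises through k = 4, and is flat between 5 and 6, while null
calibration is unaffected; k is exposed in every config.

**DA-probability mode.** "Probability of being DA decreasing in p" admits
two readings, both implemented. `one_minus_p` (default) labels a node DA
with probability 1 − p. `bum_posterior` uses the mixture's posterior
signal probability (1 − λ)a p^(a−1) / f(p). The posterior is the more
principled quantity but interacts badly with the clustering threshold: at
realistic fits (λ ≈ 0.95) the posterior of a node at p ≈ τ is only ≈ 0.5,
so even adjacent anchor pairs have co-membership ≈ 0.25 and essentially
no pair can clear a 0.8 co-membership requirement — the stage fragments
into singletons by construction. The literal 1 − p reading gives
near-one DA probabilities to significant nodes and makes the 0.8
threshold operational, so it is the default.

**Cut semantics.** The dendrogram is built by average linkage on the
distance d = 1 − M. "Cut at 0.8" is applied, by default, as a *height*
cut on that distance tree (merges while average co-membership ≥ 0.2),
which is what a standard hclust/cutree workflow at h = 0.8 computes.
The alternative reading — a similarity cut, merging only while average
co-membership ≥ 0.8 — is available as `cut_mode="similarity"`. With
sometimes-DA intermediate nodes capping pairwise co-membership near 0.5,
the similarity reading again isolates all but immediately adjacent
anchors; the height-cut reading recovers planted modules.

## Monte-Carlo and permutation design

One master seed spawns one substream per iteration (and per shuffle), so
results are independent of iteration order and bit-reproducible. Within
an iteration, randomness is consumed in fixed order — EC imputations,
metabolite imputations, Bernoulli labels — so increasing k with the same
seed can only add connections (a monotonicity the tests assert).
Connectivity requires the endpoints *and* all intermediate nodes of a
path to be DA (BFS restricted to the DA-induced subgraph). The reported
matrix is restricted to anchor rows/columns by default; restriction never
changes a retained entry.

The permutation null shuffles observed p-values within each node class,
preserving the network, the observed set, and each omic's p-value
multiset — hence the mixture fit and τ are provably invariant and are
reused rather than refitted, and every shuffle has exactly as many
anchors as the real run, just placed differently. A shuffle counts as a
success for a real module only if it yields at least as many valid
modules as the real run (global gate; a rank-matched gate is available)
and some valid shuffled module weakly dominates the real module's
(N_EC, N_met, −p̂). The pseudocount estimator (r + 1)/(B + 1) avoids
zero p-values. BH correction is applied across the *valid* (tested)
modules only; untested singletons keep q = 1, since including their
constant p = 1 would only inflate the family size without adding tests.

**Steiner completion.** Subtrees are merged greedily along globally
minimum-length inter-subtree paths, choosing uniformly among all minimal
paths (enumeration capped at 1000 per step); a path touching a third
subtree merges it too. Greedy closest-pair merging is the classic
2-approximation of the minimum Steiner tree on the metric closure; on
exhaustively solvable instances (≤ 12 nodes) the observed worst ratio is
1.33. The final module is the subgraph *induced* by the collected nodes,
so it need not be a tree.

## Synthetic benchmark: what it emulates, and what not

`generate_network` draws each metabolite's degree as Poisson(1.5) + 1
with uniformly chosen enzyme partners; the density matches the ratio of
edges to metabolite nodes (≈ 2.5) in curated microbial metabolic
networks, but the topology is otherwise homogeneous — no hub currency
metabolites, no degree heavy tails, no modular community structure.
`plant_signal` grows a connected module by random walk, draws planted
p-values from Beta(0.1, 1) and background from Uniform(0, 1), and
observes ECs at 45% and metabolites at 20%, mirroring typical projection
coverage (roughly 40–46% for ECs; metabolite coverage in real data is
far lower still, 1–4%). Planted nodes get an observability boost
(planted ECs always observed; planted metabolites at ≥ 50%): at true
metabolite coverage a 10-node planted module is information-theoretically
invisible at this scale, and the benchmark is meant to separate algorithm
failure from data starvation. Consequently, passing the benchmark shows
the pipeline recovers localized signal under its own model assumptions;
it says nothing about robustness to hub-dominated topology, correlated
p-values, or the much sparser metabolite coverage of real assays.

At the benchmark's scale (300 nodes, ~100 observed, ~5–10 signal
features), the mixture MLE is noisy: τ varies over an order of magnitude
across replicates, and the expected anchor yield per observed planted
node is only τ^0.1 ≈ 0.5. Recovery is correspondingly variable — the
best module typically reaches Jaccard ≥ 0.5 against the truth with
q < 0.1 in roughly 50–80% of replicates depending on the seed set, with
failures driven by anchor-starved fits (τ collapse) or anchor groups
separated by ≥ 4 unobserved-node edges. The problem sizes used
throughout (150 + 150 nodes, n_iter = 500, B = 50) were chosen to keep a
full benchmark replicate near two seconds while leaving Monte-Carlo
standard errors well inside the asserted tolerances.

## Degenerate inputs and edge cases

- p = 0 is clamped to 1e-10 and logged; p outside (0, 1] is an error.
- An all-identical p-value vector yields a flagged degenerate fit with
  λ forced to 1 − 1e-6.
- MLEs landing on the parameter box [1e-6, 1 − 1e-6]² are clipped and
  flagged; L-BFGS-B is run from five fixed starts because the likelihood
  can be bimodal near the boundaries (the suite checks the optimum is
  never worse than a 200 × 200 grid).
- If no τ ∈ (p_floor, 1) attains the requested FDR, a sentinel τ = 0 is
  returned with a warning: that omic contributes no anchors.
- Anchorless runs return an empty module list; single-anchor clusters
  become modules flagged invalid and are excluded from testing.
- Currency-metabolite removal never deletes enzymes and defaults to an
  explicit list (empty) rather than a degree cutoff, so hub compounds are
  never removed silently; ECs isolated by removal are retained and
  reported.
- Ties in clustering and Steiner path selection are broken
  deterministically (lexicographic node order) or by the seeded stream.

## Known limitations

- The permutation test reruns the full Monte-Carlo discovery per shuffle;
  cost is O(B · n_iter); `perm_n_iter` trades accuracy for speed and is
  labelled approximate in output.
- Module membership is hard; overlapping or soft modules are out of
  scope, as are degree-preserving edge-rewiring nulls (the null permutes
  scores, not edges).
- Unobserved nodes are imputed from the global mixture, ignoring network
  proximity to observed signal.
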