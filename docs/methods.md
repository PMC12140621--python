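# Methods

## Data representation

The package treats an HST sample as a multi-layer binary network rather
than a matrix of expression values.  Layer 1 connects each spot to its R
nearest neighbors in gene-expression principal-component space; layer 2
does the same with the 2-D spatial coordinates.  Both digraphs are
symmetrized by union (an undirected edge exists if either endpoint lists
the other), so every node has degree at least R.  Mutual-KNN
symmetrization would give degree at most R instead; union was chosen
because it preserves the "R closest neighbors" semantics for every spot
and keeps sparsely embedded spots connected.

Expression preprocessing before the embedding: library-size
normalization to the median total count, log1p, selection of the
`n_top_genes` (default 2000) most variable genes on the log-normalized
values, per-gene standardization, then PCA (deterministic full SVD).
Each step can be switched off via `PreprocessConfig`.  Defaults of 15
principal components and 2000 genes follow common single-cell practice;
HVG variance is computed before standardization (after it, all variances
are 1).

The default neighbor count is the odd integer closest to √N (ties broken
downward).  For typical sections of 2000–3000 spots this gives R ≈ 45–55,
i.e. roughly third- to fourth-order neighborhoods on a hexagonal lattice.
Odd R avoids systematic tie patterns on regular lattices.  KNN distance
ties are broken by ascending spot index (stable sort), making graph
construction bit-reproducible.

## Model and sampler

The MLSBM assumes every layer shares one label vector z and one symmetric
connectivity matrix Θ: A^l_ij | z, Θ ~ Bernoulli(θ_{z_i z_j}) for i < j.
Conjugate priors (z_i ~ Categorical(π), π ~ Dirichlet(α), θ_rs ~
Beta(β₁, β₂)) give closed-form full conditionals:

* π | z ~ Dirichlet(α_k + n_k);
* θ_rs | A, z ~ Beta(β₁ + E_rs, β₂ + n_rs − E_rs), where E_rs counts each
  unordered edge once per layer and n_rs = L·n_r·n_s (r ≠ s),
  L·n_r(n_r−1)/2 (r = s);
* z_i | z_−i categorical with ρ_ik ∝ π_k ∏_l ∏_{j≠i}
  θ_{k,z_j}^{A^l_ij}(1−θ_{k,z_j})^{1−A^l_ij}.

The pair-count convention matters: every unordered pair contributes once
per layer to both the likelihood and the conditionals, keeping the joint
density and the Gibbs updates mutually consistent (a double-counting
convention would effectively square each pairwise term for symmetric
layers).  θ values are clamped to [1e-12, 1−1e-12] inside likelihood
evaluations so log terms stay finite.

Each iteration updates π, Θ, then sweeps z sequentially and projects the
draw to canonical first-occurrence order (community 1 appears first in z,
community 2 second, …), permuting π and Θ coherently — this suppresses
label switching inside the chain, so stored draws are directly
summarizable.  The sweep is JIT-compiled (numba) over concatenated
per-layer neighbor lists; the per-site cost is O(degree + K²), which
makes chains of 10⁵+ sweeps practical on one CPU.  All randomness flows
from a single required seed (no silent default), and identical inputs
yield bit-identical chains.

Initialization uses Louvain modularity clustering on the expression
layer, coerced to exactly K groups: extra clusters are merged greedily by
smallest modularity loss; missing clusters are created by 2-means splits
of the largest cluster on its adjacency eigenvectors.  Empty communities
are allowed mid-chain (all updates remain proper); if the MAP draw
occupies fewer than K communities a warning is raised.

Point estimates: ẑ and Θ̂ are taken from the stored post-burn draw with
maximal joint log posterior (ties → earliest draw).  This keeps ẑ and Θ̂
self-consistent; an elementwise posterior-mean Θ̂ is available via
`connectivity_summary(..., estimator="mean")`.  Credible intervals are
equal-tailed empirical quantiles (HPD intervals are not implemented).
With labels fixed externally, Θ's posterior is exact Beta and summaries
are analytic.  Defaults: n_iter = 2000, burn = 1000, level = 0.95.  The
SNR summary divides the mean diagonal by the mean off-diagonal of Θ̂;
with a constant-within/constant-between design any aggregate would
coincide, and means are the least noisy under heterogeneity.

## Synthetic benchmarks

`simulate_experiment` emulates a sagittal tissue section: spots on a
triangular lattice (approximating Visium hex geometry) partitioned into
K = 5 contiguous vertical bands of near-equal size; the expression layer
is sampled from the block model at the setting's Θ (default: 0.3 within,
0.1 between, SNR 3); the spatial layer is the KNN graph of the lattice
coordinates.  Keeping the spatial layer geometry-derived rather than
SBM-sampled is deliberate: it is what produces the model's preference for
merging spatially bordering communities, the central qualitative
phenomenon the benchmarks probe.  The default n_spots = 800 is a
desk-scale stand-in for a full Visium section (~2700 spots); multi-seed
sweeps in the test-suite and acceptance script use 600–1000 Gibbs
iterations, which the exact-posterior check shows is ample for these
sizes.

Because the fitted model shares one Θ across layers while the spatial
layer has its own fixed edge density (≈0.19 within bands at n = 800),
two-layer estimates of Θ are deliberately interpreted as *network*
connectivity, not as the expression-layer generative values: at the
default design Θ̂'s diagonal sits near 0.25, between the expression 0.3
and the spatial density.  Parameter-calibration checks therefore use
`spatial_layer="sbm"`, where both layers are drawn from Θ_true and the
generative model matches the fitted one exactly; there the MAP estimate
lands within ~0.01 of the truth at n = 800 and the 95% intervals achieve
their nominal per-entry coverage.  Simultaneous coverage of all 15 unique
entries by marginal 95% intervals is necessarily far lower (≈0.95¹⁵ ≈
0.46 for near-independent entries) — a property of marginal intervals,
not of the sampler.

What the generator does **not** emulate: irregular anatomical community
shapes and sizes, spatially varying spot density, expression count
matrices (networks are simulated directly), batch effects, and
platform-specific artifacts.  Consequences observed in the benchmarks:
with equal-size bands on a regular lattice, communities are close to
maximally detectable, so recovery thresholds sit at more extreme
connectivity values than with irregular real-tissue geometry — lowering
within-community connectivity of communities 1–3 to 0.2 still yields
essentially exact recovery at n = 800 (failures set in near 0.15), and at
the elevated between-community value 0.175 an occasional single
band-boundary spot is assigned across the border because the generated
edges genuinely favor it (the flipped configuration has higher joint
posterior than the truth).  Passing these benchmarks demonstrates sampler
correctness and the spatial-merge preference; it does not by itself
guarantee thresholds observed on real tissue geometries.

## Numerical and design notes

* Exactness of the sampler is verified against an exhaustively enumerated
  collapsed posterior (all 2⁸ label vectors of an 8-node, 2-community,
  two-layer graph; total variation ≤ 0.05, measured ≈ 0.01).
* ARI (adjusted Rand index) operationalizes "correct recovery"; ARI = 1
  iff the partitions agree up to relabeling.
* Under-resolved fits are scored by `merged_pair`: the pair of true
  communities sharing a modal fitted label; a split instead of a merge
  returns None.
* Duplicate coordinates are allowed (lattices with jitter = 0 may
  collide); KNN ties resolve by index.
* Edge lists are exported 0-based with i < j; community labels are
  1-based everywhere user-facing.
* Readers validate rather than repair: asymmetric, self-looped or
  duplicated edges raise errors naming the offending file and line.

## Known limitations

* No degree correction: hub spots inflate within-community connectivity.
* One shared Θ across layers; no layer weights or layer-specific
  structure.
* K is fixed by the user, not inferred; empty communities can make the
  effective K smaller (warned).
* The canonical projection controls label switching but, like any
  relabeling scheme, cannot merge genuinely multimodal partition
  posteriors; inspect `log_post_full` for convergence.
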