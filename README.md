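# spotsbm

Community-connectivity analysis for high-throughput spatial
transcriptomics (HST) data.

Clustering tools for platforms such as 10x Visium or NanoString CosMx
return a partition of tissue spots into cell sub-populations, but say
nothing about how those sub-populations relate to one another.  `spotsbm`
quantifies that relationship: it represents the tissue as a two-layer
spot–spot similarity network (one layer from gene expression, one from
spatial position) and fits a Bayesian **multi-layer stochastic block
model** (MLSBM) whose K×K connectivity matrix Θ measures the probability
that spots in communities *r* and *s* share a nearest-neighbor edge.  The
diagonal of Θ̂ is the **within-community connectivity** (WCC — a
homogeneity measure) and the off-diagonal the **between-community
connectivity** (BCC — which flags closely related sub-populations).  It
is aimed at computational biologists doing post-hoc interpretation of HST
clusterings, whether the labels come from this model or any external tool.

## Model

With A¹ (expression KNN graph) and A² (spatial KNN graph) over N spots,

* A^l_ij | z, Θ ~ Bernoulli(θ_{z_i z_j}) independently for i < j and each layer l,
* z_i ~ Categorical(π), π ~ Dirichlet(α), θ_rs ~ Beta(β₁, β₂) for r ≤ s,

with weakly informative defaults α_k = 1, β₁ = β₂ = 1.  All full
conditionals are conjugate, so estimation is a pure Gibbs sampler; label
switching is suppressed in-chain by projecting every draw of z to
canonical first-occurrence order.  Point estimates are the maximum a
posteriori (MAP) draw; intervals are equal-tailed posterior quantiles.
The within/between ratio of Θ̂ is reported as a signal-to-noise ratio
(SNR); community structure fades as SNR → 1.

## Worked example

```python
from spotsbm import (simulate_experiment, run_gibbs, map_labels,
                     connectivity_summary, ari)

truth = simulate_experiment("default", n_spots=400, seed=1)
samples = run_gibbs(truth.graph, K=5, n_iter=1000, burn=500, seed=2)
z_map = map_labels(samples)
print(ari(z_map, truth.z_true))        # 1.0  — exact recovery of the 5 bands
summary = connectivity_summary(samples)
print(round(summary.snr, 2))           # 4.40 — estimated within/between ratio
print(summary.wcc.round(3))            # [0.268 0.248 0.238 0.232 0.277]
```

The simulated tissue has five vertical bands with expression-layer
connectivity 0.3 within and 0.1 between communities (SNR 3).  The fitted
labels match the truth exactly (adjusted Rand index 1.0).  The estimated
WCC values sit near 0.25 rather than 0.3 because the spatial layer —
a geometry-derived KNN graph — contributes its own within-band edge
density to the shared Θ; the SNR remains well above 1, signalling strong
community structure.  More narrative walkthroughs live in `examples/`
(graph construction, model fitting, external-label analysis, recovery
limits), and a thin CLI (`spotsbm simulate|fit|acc`) wraps the same
functions for shell pipelines.

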