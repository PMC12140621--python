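"""Bayesian multi-layer stochastic block model (MLSBM) with Gibbs sampling.

The model: given L binary symmetric adjacency layers over N spots sharing
one latent label vector z (z_i in {1..K}) and one K x K symmetric
connectivity matrix Theta,

    A^l_ij | z, Theta  ~  Bernoulli(theta_{z_i, z_j})   independently, i < j.

Priors are fully conjugate: z_i ~ Categorical(pi), pi ~ Dirichlet(alpha),
theta_rs ~ Beta(beta1, beta2) for r <= s, so every full conditional is in
closed form and the sampler is a pure Gibbs scheme.  Label switching is
suppressed inside the chain by projecting each draw of z to canonical
first-occurrence order (community 1 appears first in z, community 2
second, ...), with pi and Theta permuted coherently.

Labels are 1-based in the public API, matching the community numbering
used in exported tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.sparse as sp
from numba import njit
from scipy.special import betaln, gammaln
from sklearn.cluster import KMeans

from .preprocess import MultiLayerGraph

__all__ = [
    "Priors",
    "PairCounts",
    "PosteriorSamples",
    "pair_counts",
    "update_pi",
    "update_theta",
    "update_z",
    "conditional_probs",
    "canonical_relabel",
    "log_posterior",
    "init_labels",
    "run_gibbs",
    "map_labels",
]

_THETA_EPS = 1e-12


@dataclass
class Priors:
    """Conjugate hyperparameters: Dirichlet alpha for pi, Beta(beta1, beta2)
    for every theta_rs.  Defaults are the weakly informative alpha_k = 1,
    beta1 = beta2 = 1."""

    alpha: np.ndarray
    beta1: float = 1.0
    beta2: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1 or np.any(self.alpha <= 0):
            raise ValueError("alpha must be a 1-D vector of positive reals")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("beta1 and beta2 must be positive")

    @classmethod
    def default(cls, K: int) -> "Priors":
        return cls(alpha=np.ones(K))

    @property
    def K(self) -> int:
        return self.alpha.shape[0]


@dataclass
class PairCounts:
    """Observed (``edges``) and possible (``possible``) edge counts between
    each unordered community pair, summed over layers.

    possible[r, s] = L * n_r * n_s for r != s and L * n_r (n_r - 1) / 2 on
    the diagonal, counting each unordered spot pair once per layer so that
    the counts line up with the i < j support of the likelihood.
    """

    edges: np.ndarray
    possible: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.possible = np.asarray(self.possible, dtype=float)
        if self.edges.shape != self.possible.shape:
            raise ValueError("edges and possible must have the same shape")
        if np.any(self.edges < 0) or np.any(self.edges > self.possible):
            raise ValueError("need 0 <= edges <= possible elementwise")
        if not np.allclose(self.edges, self.edges.T) or not np.allclose(
            self.possible, self.possible.T
        ):
            raise ValueError("pair counts must be symmetric")


@dataclass
class PosteriorSamples:
    """Post-burn Gibbs draws of (z, pi, Theta) plus the joint log posterior.

    ``z_chain`` rows are canonical (first-occurrence order).  ``log_post``
    aligns with the stored draws; ``log_post_full`` keeps the whole-chain
    trace (including burn-in) for convergence diagnostics.
    """

    z_chain: np.ndarray
    pi_chain: np.ndarray
    theta_chain: np.ndarray
    log_post: np.ndarray
    burn: int
    seed: int
    K: int
    log_post_full: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.z_chain.shape[0]
        if not (self.pi_chain.shape[0] == self.theta_chain.shape[0] == self.log_post.shape[0] == n):
            raise ValueError("all chains must have the same number of stored draws")

    @property
    def n_stored(self) -> int:
        return self.z_chain.shape[0]

    @property
    def n_spots(self) -> int:
        return self.z_chain.shape[1]


def _check_labels(z: np.ndarray, K: int) -> np.ndarray:
    z = np.asarray(z, dtype=np.int64)
    if z.ndim != 1:
        raise ValueError("z must be a 1-D label vector")
    if z.size and (z.min() < 1 or z.max() > K):
        raise ValueError(f"labels must lie in 1..{K}")
    return z


def pair_counts(A: MultiLayerGraph, z: np.ndarray, K: int) -> PairCounts:
    """Count observed and possible edges between every community pair,
    summed over all layers, each unordered pair once per layer."""
    z = _check_labels(z, K)
    n = A.n_spots
    if z.shape[0] != n:
        raise ValueError("z is not aligned with the graph")
    one_hot = np.zeros((n, K))
    one_hot[np.arange(n), z - 1] = 1.0
    edges = np.zeros((K, K))
    for layer in A.layers:
        m = one_hot.T @ (layer @ one_hot)
        edges += m
    # symmetric adjacency counts ordered pairs within a community twice
    edges[np.diag_indices(K)] /= 2.0
    nk = np.bincount(z - 1, minlength=K).astype(float)
    possible = A.n_layers * np.outer(nk, nk)
    possible[np.diag_indices(K)] = A.n_layers * nk * (nk - 1) / 2.0
    return PairCounts(edges=edges, possible=possible)


def update_pi(z: np.ndarray, priors: Priors, rng: np.random.Generator) -> np.ndarray:
    """Draw mixture weights from their Dirichlet(alpha_k + n_k) full
    conditional; empty communities are allowed (n_k = 0)."""
    K = priors.K
    z = _check_labels(z, K)
    nk = np.bincount(z - 1, minlength=K)
    return rng.dirichlet(priors.alpha + nk)


def update_theta(counts: PairCounts, priors: Priors, rng: np.random.Generator) -> np.ndarray:
    """Draw the connectivity matrix from its Beta full conditionals:
    theta_rs ~ Beta(beta1 + edges_rs, beta2 + possible_rs - edges_rs) for
    r <= s, mirrored to the lower triangle.  A pair with no possible edges
    falls back to the prior."""
    K = counts.edges.shape[0]
    a = priors.beta1 + counts.edges
    b = priors.beta2 + counts.possible - counts.edges
    theta = np.zeros((K, K))
    iu = np.triu_indices(K)
    theta[iu] = rng.beta(a[iu], b[iu])
    theta = np.triu(theta) + np.triu(theta, 1).T
    return theta


@njit(cache=True)
def _gibbs_sweep(indptr, indices, z0, nk, L, log_theta, log_1m, log_pi, u):  # pragma: no cover
    """Sequential single-site sweep over all spots (0-based labels).

    ``indices`` concatenates the neighbor lists of all layers, so a
    neighbor appears once per layer it is connected in; nk holds current
    community sizes and is updated in place."""
    N = z0.shape[0]
    K = log_pi.shape[0]
    e = np.zeros(K, dtype=np.int64)
    logp = np.empty(K)
    for i in range(N):
        nk[z0[i]] -= 1
        for m in range(K):
            e[m] = 0
        for p in range(indptr[i], indptr[i + 1]):
            e[z0[indices[p]]] += 1
        best = -1e300
        for k in range(K):
            s = log_pi[k]
            for m in range(K):
                em = e[m]
                s += em * log_theta[k, m] + (L * nk[m] - em) * log_1m[k, m]
            logp[k] = s
            if s > best:
                best = s
        tot = 0.0
        for k in range(K):
            logp[k] = np.exp(logp[k] - best)
            tot += logp[k]
        r = u[i] * tot
        acc = 0.0
        new = K - 1
        for k in range(K):
            acc += logp[k]
            if r < acc:
                new = k
                break
        z0[i] = new
        nk[new] += 1


def _concat_neighbors(A: MultiLayerGraph) -> tuple[np.ndarray, np.ndarray]:
    """Merge all layers' CSR neighbor lists into one multiset per node."""
    n = A.n_spots
    indptrs = [layer.indptr for layer in A.layers]
    counts = np.zeros(n + 1, dtype=np.int64)
    for ptr in indptrs:
        counts[1:] += np.diff(ptr)
    indptr = np.cumsum(counts)
    indices = np.empty(indptr[-1], dtype=np.int64)
    pos = indptr[:-1].copy()
    for layer in A.layers:
        for i in range(n):
            row = layer.indices[layer.indptr[i]: layer.indptr[i + 1]]
            indices[pos[i]: pos[i] + row.size] = row
            pos[i] += row.size
    return indptr, indices


def _clamped_log_theta(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.clip(theta, _THETA_EPS, 1.0 - _THETA_EPS)
    return np.log(t), np.log1p(-t)


def update_z(
    A: MultiLayerGraph,
    z: np.ndarray,
    pi: np.ndarray,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One full sequential Gibbs sweep of the labels.

    Each z_i is redrawn from its exact categorical full conditional
    rho_ik proportional to pi_k * prod_l prod_{j != i}
    theta_{k,z_j}^{A^l_ij} (1 - theta_{k,z_j})^{1 - A^l_ij},
    evaluated in log space with each unordered pair counted once per
    layer.  Returns a new label vector; the input is not modified.
    """
    K = pi.shape[0]
    z = _check_labels(z, K)
    indptr, indices = _concat_neighbors(A)
    log_theta, log_1m = _clamped_log_theta(theta)
    z0 = z - 1
    nk = np.bincount(z0, minlength=K).astype(np.int64)
    _gibbs_sweep(
        indptr, indices, z0, nk, A.n_layers, log_theta, log_1m,
        np.log(np.clip(pi, 1e-300, None)), rng.random(z.shape[0]),
    )
    return z0 + 1


def conditional_probs(
    A: MultiLayerGraph, z: np.ndarray, i: int, pi: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Exact full-conditional probabilities P(z_i = k | z_-i, A, pi, Theta).

    Diagnostic companion to :func:`update_z`; the sweep draws from exactly
    these categoricals site by site.
    """
    K = pi.shape[0]
    z = _check_labels(z, K)
    log_theta, log_1m = _clamped_log_theta(theta)
    others = np.delete(np.arange(z.shape[0]), i)
    zo = z[others] - 1
    logp = np.log(np.clip(pi, 1e-300, None)).copy()
    for layer in A.layers:
        row = np.asarray(layer[i].todense()).ravel()[others]
        for k in range(K):
            logp[k] += np.sum(row * log_theta[k, zo] + (1 - row) * log_1m[k, zo])
    p = np.exp(logp - logp.max())
    return p / p.sum()


def canonical_relabel(
    z: np.ndarray, pi: np.ndarray | None = None, theta: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Project to canonical first-occurrence order: relabel so community 1
    appears first in z, community 2 second, etc.; pi's entries and Theta's
    rows/columns are permuted by the same map.  Idempotent.

    Labels absent from z keep their relative order after the present ones,
    so the permutation is always a full bijection on 1..K.
    """
    z = np.asarray(z, dtype=np.int64)
    K = pi.shape[0] if pi is not None else int(z.max())
    _check_labels(z, K)
    _, first = np.unique(z, return_index=True)
    present = z[np.sort(first)]  # old labels in order of first occurrence
    absent = [k for k in range(1, K + 1) if k not in set(present.tolist())]
    old_order = np.concatenate([present, np.asarray(absent, dtype=np.int64)])
    perm = np.empty(K + 1, dtype=np.int64)  # old label -> new label
    perm[old_order] = np.arange(1, K + 1)
    z_new = perm[z]
    pi_new = theta_new = None
    if pi is not None:
        pi_new = np.asarray(pi)[old_order - 1]
    if theta is not None:
        t = np.asarray(theta)
        theta_new = t[np.ix_(old_order - 1, old_order - 1)]
    return z_new, pi_new, theta_new


def _log_prior_density(pi: np.ndarray, theta: np.ndarray, priors: Priors) -> float:
    alpha = priors.alpha
    pi_c = np.clip(pi, _THETA_EPS, None)
    pi_c = pi_c / pi_c.sum()
    log_dir = gammaln(alpha.sum()) - gammaln(alpha).sum() + np.sum((alpha - 1) * np.log(pi_c))
    t = np.clip(theta, _THETA_EPS, 1.0 - _THETA_EPS)
    iu = np.triu_indices(theta.shape[0])
    log_beta = np.sum(
        (priors.beta1 - 1) * np.log(t[iu])
        + (priors.beta2 - 1) * np.log1p(-t[iu])
        - betaln(priors.beta1, priors.beta2)
    )
    return float(log_dir + log_beta)


def _log_posterior_from_counts(
    counts: PairCounts, z: np.ndarray, pi: np.ndarray, theta: np.ndarray, priors: Priors
) -> float:
    log_theta, log_1m = _clamped_log_theta(theta)
    iu = np.triu_indices(theta.shape[0])
    lik = np.sum(
        counts.edges[iu] * log_theta[iu]
        + (counts.possible[iu] - counts.edges[iu]) * log_1m[iu]
    )
    nk = np.bincount(z - 1, minlength=pi.shape[0])
    lab = np.sum(nk * np.log(np.clip(pi, 1e-300, None)))
    return float(lik + lab) + _log_prior_density(pi, theta, priors)


def log_posterior(
    A: MultiLayerGraph,
    z: np.ndarray,
    pi: np.ndarray,
    theta: np.ndarray,
    priors: Priors,
) -> float:
    """Joint log posterior density (up to the constant marginal of A):
    Bernoulli likelihood over all i < j pairs and layers, categorical
    label prior, Dirichlet and Beta prior densities.  Theta is clamped
    into (0, 1) so the value is always finite."""
    K = pi.shape[0]
    counts = pair_counts(A, z, K)
    return _log_posterior_from_counts(counts, z, pi, theta, priors)


def _merge_to_k(G: nx.Graph, communities: list[set], K: int) -> list[set]:
    """Greedily merge the community pair whose merge best preserves
    modularity until exactly K remain."""
    communities = [set(c) for c in communities]
    while len(communities) > K:
        best = None
        best_q = -np.inf
        for a in range(len(communities)):
            for b in range(a + 1, len(communities)):
                trial = [c for idx, c in enumerate(communities) if idx not in (a, b)]
                trial.append(communities[a] | communities[b])
                q = nx.algorithms.community.modularity(G, trial)
                if q > best_q:
                    best_q = q
                    best = (a, b)
        a, b = best
        merged = communities[a] | communities[b]
        communities = [c for idx, c in enumerate(communities) if idx not in (a, b)]
        communities.append(merged)
    return communities


def _split_to_k(A1: sp.csr_matrix, communities: list[set], K: int, seed: int) -> list[set]:
    """Split the largest community by 2-means on the leading eigenvectors
    of its induced adjacency until exactly K communities exist."""
    communities = [set(c) for c in communities]
    while len(communities) < K:
        communities.sort(key=lambda c: (-len(c), min(c)))
        big = sorted(communities.pop(0))
        if len(big) < 2:
            raise ValueError("cannot split a singleton community further")
        sub = A1[np.ix_(big, big)].toarray().astype(float)
        vals, vecs = np.linalg.eigh(sub)
        feats = vecs[:, -2:] if sub.shape[0] > 1 else vecs
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        part = km.fit_predict(feats)
        if len(set(part)) < 2:  # degenerate geometry: split by index halves
            part = (np.arange(len(big)) >= len(big) // 2).astype(int)
        left = {big[i] for i in range(len(big)) if part[i] == 0}
        right = set(big) - left
        communities.extend([left, right])
    return communities


def init_labels(A1: sp.csr_matrix, K: int, seed: int) -> np.ndarray:
    """Initialize labels by Louvain modularity clustering on the expression
    layer, then merge or split clusters to exactly K non-empty groups.

    Deterministic given ``seed``; returns canonical 1-based labels.
    """
    A1 = sp.csr_matrix(A1)
    n = A1.shape[0]
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of nodes ({n})")
    if K == 1:
        return np.ones(n, dtype=np.int64)
    if K == n:
        return np.arange(1, n + 1, dtype=np.int64)
    G = nx.from_scipy_sparse_array(A1)
    communities = [set(c) for c in nx.algorithms.community.louvain_communities(G, seed=seed)]
    if len(communities) > K:
        communities = _merge_to_k(G, communities, K)
    elif len(communities) < K:
        communities = _split_to_k(A1, communities, K, seed)
    z = np.zeros(n, dtype=np.int64)
    for label, members in enumerate(communities, start=1):
        z[sorted(members)] = label
    z, _, _ = canonical_relabel(z, np.ones(K) / K, np.zeros((K, K)))
    return z


def run_gibbs(
    A: MultiLayerGraph,
    K: int,
    priors: Priors | None = None,
    n_iter: int = 2000,
    burn: int = 1000,
    seed: int | None = None,
    z_init: np.ndarray | None = None,
    log_every: int = 0,
) -> PosteriorSamples:
    """Run the full Gibbs sampler and return post-burn draws.

    Each iteration updates pi (Dirichlet), Theta (Beta), then sweeps z
    (categorical full conditionals) and projects to canonical label
    order.  Fully reproducible: all randomness flows from ``seed``.

    Parameters
    ----------
    A : MultiLayerGraph
        Validated multi-layer adjacency (symmetric binary layers).
    K : int
        Number of communities to fit.
    priors : Priors, optional
        Defaults to alpha_k = 1, beta1 = beta2 = 1.
    n_iter, burn : int
        Total sweeps and discarded warm-up sweeps (burn < n_iter).
    seed : int
        Required; there is no silent default.
    z_init : array, optional
        Starting labels (1..K); defaults to Louvain-based initialization
        on layer 1.
    log_every : int
        If positive, print iteration, log posterior and occupied-community
        count every ``log_every`` sweeps.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    if not 0 <= burn < n_iter:
        raise ValueError("need 0 <= burn < n_iter")
    if K < 1:
        raise ValueError("K must be at least 1")
    A.validate()
    priors = priors or Priors.default(K)
    if priors.K != K:
        raise ValueError("priors.alpha length must equal K")
    rng = np.random.default_rng(seed)
    if z_init is None:
        z = init_labels(A.layers[0], K, seed)
    else:
        z = _check_labels(z_init, K).copy()
        z, _, _ = canonical_relabel(z, np.ones(K) / K, np.zeros((K, K)))

    n = A.n_spots
    indptr, indices = _concat_neighbors(A)
    L = A.n_layers
    n_stored = n_iter - burn
    z_chain = np.empty((n_stored, n), dtype=np.int16)
    pi_chain = np.empty((n_stored, K))
    theta_chain = np.empty((n_stored, K, K))
    log_post = np.empty(n_stored)
    log_post_full = np.empty(n_iter)

    counts = pair_counts(A, z, K)
    alpha = priors.alpha
    for it in range(n_iter):
        nk = np.bincount(z - 1, minlength=K)
        pi = rng.dirichlet(alpha + nk)
        theta = update_theta(counts, priors, rng)
        log_theta, log_1m = _clamped_log_theta(theta)
        z0 = z - 1
        nk64 = nk.astype(np.int64)
        _gibbs_sweep(
            indptr, indices, z0, nk64, L, log_theta, log_1m,
            np.log(np.clip(pi, 1e-300, None)), rng.random(n),
        )
        z, pi, theta = canonical_relabel(z0 + 1, pi, theta)
        counts = pair_counts(A, z, K)
        lp = _log_posterior_from_counts(counts, z, pi, theta, priors)
        log_post_full[it] = lp
        if it >= burn:
            s = it - burn
            z_chain[s] = z
            pi_chain[s] = pi
            theta_chain[s] = theta
            log_post[s] = lp
        if log_every and (it + 1) % log_every == 0:
            occ = int(np.count_nonzero(np.bincount(z - 1, minlength=K)))
            print(f"iter {it + 1:6d}  log_post {lp:14.3f}  occupied {occ}/{K}")

    samples = PosteriorSamples(
        z_chain=z_chain, pi_chain=pi_chain, theta_chain=theta_chain,
        log_post=log_post, burn=burn, seed=seed, K=K, log_post_full=log_post_full,
    )
    occupied = len(np.unique(z_chain[int(np.argmax(log_post))]))
    if occupied < K:
        warnings.warn(
            f"MAP draw occupies only {occupied} of K={K} communities", stacklevel=2
        )
    return samples


def map_labels(samples: PosteriorSamples) -> np.ndarray:
    """Maximum a posteriori labels: the stored post-burn draw of z with the
    largest joint log posterior (ties resolved to the earliest draw)."""
    if samples.n_stored == 0:
        raise ValueError("posterior chain is empty")
    return samples.z_chain[int(np.argmax(samples.log_post))].astype(np.int64)
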