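"""Chain-level machinery: canonical projection, log posterior, Louvain
initialization, the full Gibbs loop and MAP extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spotsbm import (
    Priors,
    canonical_relabel,
    init_labels,
    log_posterior,
    map_labels,
    run_gibbs,
)
from conftest import graph_from_edges, random_multilayer


def brute_log_posterior(A, z, pi, theta, priors):
    """Naive double-loop likelihood plus prior densities."""
    from scipy.special import betaln, gammaln

    eps = 1e-12
    t = np.clip(theta, eps, 1 - eps)
    n = A.n_spots
    lik = 0.0
    for layer in A.layers:
        d = layer.toarray()
        for i in range(n):
            for j in range(i + 1, n):
                p = t[z[i] - 1, z[j] - 1]
                lik += np.log(p) if d[i, j] else np.log1p(-p)
    lik += sum(np.log(pi[z[i] - 1]) for i in range(n))
    alpha = priors.alpha
    lik += gammaln(alpha.sum()) - gammaln(alpha).sum() + np.sum((alpha - 1) * np.log(pi))
    K = theta.shape[0]
    for r in range(K):
        for s in range(r, K):
            lik += (
                (priors.beta1 - 1) * np.log(t[r, s])
                + (priors.beta2 - 1) * np.log1p(-t[r, s])
                - betaln(priors.beta1, priors.beta2)
            )
    return lik


class TestCanonicalRelabel:
    def test_forced_reordering(self):
        z = np.array([2, 2, 1, 3])
        pi = np.array([0.2, 0.5, 0.3])
        theta = np.array([[0.1, 0.2, 0.3], [0.2, 0.4, 0.5], [0.3, 0.5, 0.6]])
        z2, pi2, th2 = canonical_relabel(z, pi, theta)
        np.testing.assert_array_equal(z2, [1, 1, 2, 3])
        np.testing.assert_allclose(pi2, [0.5, 0.2, 0.3])  # labels 2,1,3 -> 1,2,3
        np.testing.assert_allclose(th2[0, 0], 0.4)
        np.testing.assert_allclose(th2[0, 1], 0.2)

    def test_idempotent(self):
        z = np.array([1, 1, 2, 3, 2])
        pi = np.array([0.3, 0.3, 0.4])
        theta = np.full((3, 3), 0.2)
        out = canonical_relabel(z, pi, theta)
        again = canonical_relabel(*out)
        np.testing.assert_array_equal(out[0], again[0])
        np.testing.assert_allclose(out[1], again[1])
        np.testing.assert_allclose(out[2], again[2])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_log_posterior_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n, K = 9, 3
        g = random_multilayer(n, seed=seed)
        z = rng.integers(1, K + 1, size=n)
        pi = rng.dirichlet(np.ones(K))
        theta = rng.uniform(0.05, 0.95, size=(K, K))
        theta = (theta + theta.T) / 2
        priors = Priors.default(K)
        before = log_posterior(g, z, pi, theta, priors)
        z2, pi2, th2 = canonical_relabel(z, pi, theta)
        after = log_posterior(g, z2, pi2, th2, priors)
        assert after == pytest.approx(before, abs=1e-9)


class TestLogPosterior:
    def test_empty_graph_half_probability_closed_form(self):
        n, K = 6, 2
        g = graph_from_edges(n, [], [])
        pi = np.ones(K) / K
        theta = np.full((K, K), 0.5)
        priors = Priors.default(K)
        lp = log_posterior(g, np.ones(n, dtype=int), pi, theta, priors)
        lik = -2 * n * (n - 1) / 2 * np.log(2)  # L * N(N-1)/2 pairs at log(1/2)
        label_prior = n * np.log(0.5)
        prior = brute_log_posterior(g, np.ones(n, dtype=int), pi, theta, priors) - (
            lik + label_prior
        )
        assert lp == pytest.approx(lik + label_prior + prior, abs=1e-9)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n, K = 10, 3
        g = random_multilayer(n, seed=seed + 1)
        z = rng.integers(1, K + 1, size=n)
        pi = rng.dirichlet(np.ones(K))
        theta = rng.uniform(0.05, 0.95, size=(K, K))
        theta = (theta + theta.T) / 2
        priors = Priors.default(K)
        assert log_posterior(g, z, pi, theta, priors) == pytest.approx(
            brute_log_posterior(g, z, pi, theta, priors), abs=1e-10
        )


class TestInitLabels:
    def test_two_cliques_split(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        g = graph_from_edges(10, edges)
        z = init_labels(g.layers[0], K=2, seed=0)
        assert len(np.unique(z)) == 2
        assert len(set(z[:5])) == 1 and len(set(z[5:])) == 1
        assert z[0] != z[5]

    def test_k_one_and_k_n(self):
        g = random_multilayer(7, seed=10)
        np.testing.assert_array_equal(init_labels(g.layers[0], 1, seed=0), np.ones(7))
        np.testing.assert_array_equal(
            init_labels(g.layers[0], 7, seed=0), np.arange(1, 8)
        )

    def test_forces_exactly_k_groups(self):
        g = random_multilayer(20, p=0.3, seed=11)
        for k in (2, 3, 6):
            z = init_labels(g.layers[0], k, seed=1)
            assert len(np.unique(z)) == k

    def test_k_above_n_rejected(self):
        g = random_multilayer(4, seed=12)
        with pytest.raises(ValueError):
            init_labels(g.layers[0], 5, seed=0)


class TestRunGibbs:
    def test_k1_theta_chain_has_conjugate_mean(self):
        g = random_multilayer(10, p=0.35, seed=13)
        samples = run_gibbs(g, K=1, n_iter=3000, burn=500, seed=14)
        assert (samples.z_chain == 1).all()
        total_pairs = 2 * 10 * 9 / 2
        total_edges = sum(layer.nnz / 2 for layer in g.layers)
        expected = (1 + total_edges) / (2 + total_pairs)
        chain = samples.theta_chain[:, 0, 0]
        se = chain.std() / np.sqrt(len(chain) / 10)  # conservative for autocorr
        assert abs(chain.mean() - expected) < 4 * max(se, 1e-3)

    def test_reproducible_and_canonical(self):
        g = random_multilayer(12, seed=15)
        s1 = run_gibbs(g, K=3, n_iter=80, burn=20, seed=16)
        s2 = run_gibbs(g, K=3, n_iter=80, burn=20, seed=16)
        np.testing.assert_array_equal(s1.z_chain, s2.z_chain)
        np.testing.assert_allclose(s1.theta_chain, s2.theta_chain)
        np.testing.assert_allclose(s1.log_post, s2.log_post)
        for z in s1.z_chain:
            zc, _, _ = canonical_relabel(z.astype(np.int64))
            np.testing.assert_array_equal(z, zc)

    def test_requires_seed_and_valid_burn(self):
        g = random_multilayer(6, seed=17)
        with pytest.raises(ValueError):
            run_gibbs(g, K=2, n_iter=10, burn=2, seed=None)
        with pytest.raises(ValueError):
            run_gibbs(g, K=2, n_iter=10, burn=10, seed=1)


class TestMapLabels:
    def test_argmax_agrees_with_independent_reevaluation(self):
        g = random_multilayer(10, seed=18)
        samples = run_gibbs(g, K=2, n_iter=120, burn=40, seed=19)
        z_map = map_labels(samples)
        priors = Priors.default(2)
        recomputed = [
            log_posterior(
                g,
                samples.z_chain[i].astype(np.int64),
                samples.pi_chain[i],
                samples.theta_chain[i],
                priors,
            )
            for i in range(samples.n_stored)
        ]
        np.testing.assert_allclose(recomputed, samples.log_post, atol=1e-8)
        np.testing.assert_array_equal(
            z_map, samples.z_chain[int(np.argmax(recomputed))]
        )

    def test_singleton_chain(self):
        g = random_multilayer(6, seed=20)
        samples = run_gibbs(g, K=2, n_iter=5, burn=4, seed=21)
        np.testing.assert_array_equal(map_labels(samples), samples.z_chain[0])
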