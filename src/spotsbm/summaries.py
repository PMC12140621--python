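"""Community-connectivity summaries from posterior samples or fixed labels.

The object of inference is the K x K connectivity matrix Theta: theta_rs
is the probability that a randomly chosen spot in community r shares a
nearest-neighbor edge with a spot in community s.  The diagonal gives
within-community connectivity (WCC, a homogeneity measure: heterogeneous
communities have lower WCC) and the off-diagonal gives between-community
connectivity (BCC, which flags closely related communities).  The
signal-to-noise ratio (SNR) is the ratio of within- to between-community
connectivity; structure fades as SNR approaches 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MultiLayerGraph
from .sbm import PairCounts, PosteriorSamples, Priors, canonical_relabel, pair_counts

__all__ = ["ACCSummary", "connectivity_summary", "snr_estimate", "external_labels_acc"]


@dataclass
class ACCSummary:
    """Point estimates and equal-tailed credible intervals for Theta.

    ``wcc`` is the diagonal of ``theta_hat``; ``bcc`` holds the upper
    off-diagonal entries in the row-major order given by ``pairs``.
    Interval bounds are stored as full K x K matrices aligned with
    ``theta_hat``.
    """

    theta_hat: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    snr: float

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)
        K = self.theta_hat.shape[0]
        if self.theta_hat.shape != (K, K):
            raise ValueError("theta_hat must be square")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        tol = 1e-9
        if np.any(self.ci_lower > self.theta_hat + tol) or np.any(
            self.ci_upper < self.theta_hat - tol
        ):
            raise ValueError("intervals must bracket the point estimates")

    @property
    def K(self) -> int:
        return self.theta_hat.shape[0]

    @property
    def wcc(self) -> np.ndarray:
        return np.diag(self.theta_hat)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        K = self.K
        return [(r + 1, s + 1) for r in range(K) for s in range(r + 1, K)]

    @property
    def bcc(self) -> np.ndarray:
        iu = np.triu_indices(self.K, k=1)
        return self.theta_hat[iu]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per unordered community pair (r, s) with the
        estimate, interval and WCC/BCC kind."""
        rows = []
        K = self.K
        for r in range(K):
            for s in range(r, K):
                rows.append(
                    {
                        "r": r + 1,
                        "s": s + 1,
                        "estimate": self.theta_hat[r, s],
                        "lower": self.ci_lower[r, s],
                        "upper": self.ci_upper[r, s],
                        "kind": "WCC" if r == s else "BCC",
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "wcc": self.wcc.tolist(),
            "bcc": self.bcc.tolist(),
            "pairs": self.pairs,
            "level": self.level,
            "snr": self.snr,
        }


def snr_estimate(theta: np.ndarray) -> float:
    """Within- over between-community connectivity: mean of the diagonal of
    Theta divided by the mean of its off-diagonal entries.  Returns +inf
    when the off-diagonal mean is zero."""
    theta = np.asarray(theta, dtype=float)
    K = theta.shape[0]
    if K < 2:
        raise ValueError("SNR requires at least two communities")
    within = float(np.mean(np.diag(theta)))
    off = theta[~np.eye(K, dtype=bool)]
    between = float(np.mean(off))
    if between == 0.0:
        return float("inf")
    return within / between


def connectivity_summary(
    samples: PosteriorSamples, level: float = 0.95, estimator: str = "map"
) -> ACCSummary:
    """Summarize the posterior of Theta from a Gibbs chain.

    ``estimator="map"`` (default) reports the Theta stored at the draw
    with maximal joint log posterior, self-consistent with the MAP labels;
    ``"mean"`` reports the elementwise posterior mean.  Intervals are
    equal-tailed empirical quantiles of each theta_rs chain.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if samples.n_stored == 0:
        raise ValueError("posterior chain is empty")
    chain = samples.theta_chain
    if estimator == "map":
        theta_hat = chain[int(np.argmax(samples.log_post))]
    elif estimator == "mean":
        theta_hat = chain.mean(axis=0)
    else:
        raise ValueError("estimator must be 'map' or 'mean'")
    tail = (1.0 - level) / 2.0
    lower = np.quantile(chain, tail, axis=0)
    upper = np.quantile(chain, 1.0 - tail, axis=0)
    # a point estimate can fall outside the equal-tailed band only through
    # MAP-vs-quantile disagreement; widen minimally to keep the contract
    lower = np.minimum(lower, theta_hat)
    upper = np.maximum(upper, theta_hat)
    snr = snr_estimate(theta_hat) if theta_hat.shape[0] >= 2 else float("nan")
    return ACCSummary(theta_hat=theta_hat, ci_lower=lower, ci_upper=upper, level=level, snr=snr)


def external_labels_acc(
    A: MultiLayerGraph,
    z_ext: np.ndarray,
    priors: Priors | None = None,
    level: float = 0.95,
    n_draws: int = 0,
    seed: int | None = None,
) -> ACCSummary:
    """Connectivity analysis with labels held fixed at an external
    clustering (any upstream method's output).

    With z fixed, each theta_rs posterior is exactly
    Beta(beta1 + edges_rs, beta2 + possible_rs - edges_rs); the point
    estimate is the posterior mean and intervals are analytic Beta
    quantiles.  If ``n_draws`` > 0, Monte Carlo draws are used instead of
    the closed form (mainly for cross-checking).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = np.asarray(z_ext, dtype=np.int64)
    if z.shape[0] != A.n_spots:
        raise ValueError("labels are not aligned with the graph")
    if z.min() < 1:
        raise ValueError("labels must be positive integers (1-based)")
    z, _, _ = canonical_relabel(z)
    K = int(z.max())
    if not np.array_equal(np.unique(z), np.arange(1, K + 1)):
        raise ValueError("labels must occupy 1..K after canonicalization")
    priors = priors or Priors.default(K)
    counts: PairCounts = pair_counts(A, z, K)
    a = priors.beta1 + counts.edges
    b = priors.beta2 + counts.possible - counts.edges
    tail = (1.0 - level) / 2.0
    if n_draws > 0:
        rng = np.random.default_rng(seed)
        draws = rng.beta(a, b, size=(n_draws, K, K))
        upper = np.triu(draws)  # one draw per unordered pair, mirrored
        draws = upper + np.triu(draws, 1).transpose(0, 2, 1)
        theta_hat = draws.mean(axis=0)
        lower = np.quantile(draws, tail, axis=0)
        upper = np.quantile(draws, 1.0 - tail, axis=0)
    else:
        theta_hat = a / (a + b)
        lower = stats.beta.ppf(tail, a, b)
        upper = stats.beta.ppf(1.0 - tail, a, b)
    snr = snr_estimate(theta_hat) if K >= 2 else float("nan")
    return ACCSummary(theta_hat=theta_hat, ci_lower=lower, ci_upper=upper, level=level, snr=snr)


def posterior_sd(A: MultiLayerGraph, z: np.ndarray, priors: Priors | None = None) -> np.ndarray:
    """Elementwise posterior standard deviation of Theta for fixed labels
    (exact Beta moments); convenience for calibration checks."""
    z = np.asarray(z, dtype=np.int64)
    z, _, _ = canonical_relabel(z)
    K = int(z.max())
    priors = priors or Priors.default(K)
    counts = pair_counts(A, z, K)
    a = priors.beta1 + counts.edges
    b = priors.beta2 + counts.possible - counts.edges
    return np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
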