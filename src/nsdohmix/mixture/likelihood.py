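"""Multivariate Bernoulli mixture: likelihoods, priors, conjugate marginals.

The model: each tract i belongs to a latent profile z_i with
P(z_i = k) = pi_k, and given z_i = k each binary indicator x_ij is an
independent Bernoulli(theta_{j|k}).  Priors: K ~ Poisson(lambda) truncated to
{1..K_max}; pi | K ~ Dirichlet(gamma, ..., gamma); theta_{j|k} ~ Beta(alpha,
beta).  Conjugacy lets pi and theta be integrated out analytically, so the
sampler only ever tracks the allocations z and the sufficient statistics
(n_k, s_jk) = (rows per component, per-component column sums).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import betaln, gammaln, logsumexp


@dataclass(frozen=True)
class MixturePrior:
    """Hyperparameters of the mixture prior (defaults: lam=1, K_max=50, gamma=alpha=beta=1)."""

    lam: float = 1.0
    k_max: int = 50
    gamma: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if min(self.gamma, self.alpha, self.beta) <= 0:
            raise ValueError("gamma, alpha, beta must be positive")

    @cached_property
    def _log_k_norm(self) -> float:
        ks = np.arange(1, self.k_max + 1)
        return float(logsumexp(ks * np.log(self.lam) - gammaln(ks + 1)))

    def log_k_prior(self, k: int) -> float:
        """log p(K = k) under the truncated Poisson prior."""
        if not 1 <= k <= self.k_max:
            return -np.inf
        return k * np.log(self.lam) - float(gammaln(k + 1)) - self._log_k_norm


@dataclass
class MixtureParams:
    """Explicit component parameters (pi, theta) at a fixed K."""

    k: int
    pi: np.ndarray
    theta: np.ndarray  # (p, K)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.k < 1 or self.pi.shape != (self.k,):
            raise ValueError("pi must have length K >= 1")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if (self.pi < 0).any():
            raise ValueError("pi must be nonnegative")
        if self.theta.ndim != 2 or self.theta.shape[1] != self.k:
            raise ValueError("theta must be p x K")
        if (self.theta < 0).any() or (self.theta > 1).any():
            raise ValueError("theta entries must lie in [0, 1]")


@dataclass
class AllocationState:
    """Allocations z plus the sufficient statistics the collapsed math needs."""

    z: np.ndarray
    n_k: np.ndarray
    s_jk: np.ndarray  # (K, p) per-component success counts

    @classmethod
    def from_z(cls, z: np.ndarray, x: np.ndarray, k: int) -> "AllocationState":
        z = np.asarray(z, dtype=np.int64)
        x = np.asarray(x)
        if z.min(initial=0) < 0 or (z.size and z.max() >= k):
            raise ValueError("labels must lie in 0..K-1")
        n_k = np.bincount(z, minlength=k).astype(np.int64)
        s_jk = np.zeros((k, x.shape[1]), dtype=np.int64)
        np.add.at(s_jk, z, x.astype(np.int64))
        return cls(z.copy(), n_k, s_jk)

    @property
    def k(self) -> int:
        return int(self.n_k.shape[0])

    @property
    def n(self) -> int:
        return int(self.z.shape[0])

    @property
    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.n_k > 0)

    @property
    def n_nonempty(self) -> int:
        return int((self.n_k > 0).sum())

    def validate_against(self, x: np.ndarray) -> None:
        ref = AllocationState.from_z(self.z, x, self.k)
        if not (np.array_equal(ref.n_k, self.n_k) and np.array_equal(ref.s_jk, self.s_jk)):
            raise ValueError("sufficient statistics inconsistent with z and X")
        if (self.s_jk < 0).any() or (self.s_jk > self.n_k[:, None]).any():
            raise ValueError("sufficient statistics out of range")

    def remove_row(self, i: int, x_row: np.ndarray) -> int:
        k = int(self.z[i])
        self.n_k[k] -= 1
        self.s_jk[k] -= x_row
        self.z[i] = -1
        return k

    def add_row(self, i: int, k: int, x_row: np.ndarray) -> None:
        self.z[i] = k
        self.n_k[k] += 1
        self.s_jk[k] += x_row

    def copy(self) -> "AllocationState":
        return AllocationState(self.z.copy(), self.n_k.copy(), self.s_jk.copy())


def _per_component_loglik(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log P(x_i | z_i = k), robust to theta in {0, 1}."""
    x = np.asarray(x, dtype=np.uint8)
    n, p = x.shape
    k = theta.shape[1]
    out = np.empty((n, k))
    with np.errstate(divide="ignore"):
        lt = np.log(theta)
        l1t = np.log1p(-theta)
    for kk in range(k):
        out[:, kk] = np.where(x == 1, lt[:, kk], l1t[:, kk]).sum(axis=1)
    return out


def log_observed_likelihood(x: np.ndarray | object, params: MixtureParams) -> float:
    """log of the observed-data likelihood, sum_i log sum_k pi_k prod_j Bern.

    Returns -inf (not an exception) when some row has probability 0 under
    every component.
    """
    x = getattr(x, "values", x)
    if np.asarray(x).shape[1] != params.theta.shape[0]:
        raise ValueError("X and theta dimensions disagree")
    row_k = _per_component_loglik(x, params.theta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
    return float(logsumexp(row_k + log_pi[None, :], axis=1).sum())


def log_complete_likelihood(
    x: np.ndarray | object, z: np.ndarray, params: MixtureParams
) -> float:
    """log of the complete-data likelihood for fixed allocations z."""
    x = getattr(x, "values", x)
    z = np.asarray(z, dtype=np.int64)
    if z.min() < 0 or z.max() >= params.k:
        raise ValueError("z labels out of range")
    row_k = _per_component_loglik(x, params.theta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
    return float((row_k[np.arange(len(z)), z] + log_pi[z]).sum())


def collapsed_joint_from_stats(
    n_k: np.ndarray, s_jk: np.ndarray, prior: MixturePrior
) -> float:
    """log p(X, z | K) with pi and theta integrated out, from (n_k, s_jk)."""
    k = n_k.shape[0]
    n = int(n_k.sum())
    g, a, b = prior.gamma, prior.alpha, prior.beta
    out = gammaln(k * g) - gammaln(k * g + n)
    out += (gammaln(n_k + g) - gammaln(g)).sum()
    out += (betaln(a + s_jk, b + (n_k[:, None] - s_jk)) - betaln(a, b)).sum()
    return float(out)


def log_collapsed_joint(
    x: np.ndarray | object,
    state: AllocationState,
    prior: MixturePrior,
    validate: bool = False,
) -> float:
    """log p(X, z | K) for the allocations in ``state`` (K = state.k)."""
    if validate:
        state.validate_against(getattr(x, "values", x))
    return collapsed_joint_from_stats(state.n_k, state.s_jk, prior)


def gibbs_full_conditional(
    i: int, state: AllocationState, x: np.ndarray | object, prior: MixturePrior
) -> np.ndarray:
    """p(z_i = k | z_{-i}, X, K) as a length-K probability vector.

    Proportional to (n_k + gamma) * prod_j (alpha + s_jk)^{x_ij}
    (beta + n_k - s_jk)^{1 - x_ij} / (alpha + beta + n_k), with counts taken
    with row i removed.
    """
    x = getattr(x, "values", x)
    x_row = np.asarray(x)[i].astype(np.int64)
    work = state.copy()
    work.remove_row(i, x_row)
    logw = gibbs_log_weights(x_row, work.n_k, work.s_jk, prior)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def gibbs_log_weights(
    x_row: np.ndarray, n_k: np.ndarray, s_jk: np.ndarray, prior: MixturePrior
) -> np.ndarray:
    """Unnormalized log full-conditional weights given row-deleted counts."""
    p = s_jk.shape[1]
    a, b, g = prior.alpha, prior.beta, prior.gamma
    num = np.where(x_row[None, :] == 1, a + s_jk, b + (n_k[:, None] - s_jk))
    return (
        np.log(n_k + g)
        - p * np.log(a + b + n_k)
        + np.log(num).sum(axis=1)
    )
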