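"""Exact posterior over (K, z) by exhaustive enumeration on tiny instances.

Feasible only for a handful of rows and small K_max (the state space has
sum_K K^n terms), but on such instances it gives the ground-truth posterior
the sampler must reproduce.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp

from .likelihood import AllocationState, MixturePrior, collapsed_joint_from_stats


def enumerate_log_posterior(
    x: np.ndarray | object, prior: MixturePrior
) -> list[tuple[int, tuple[int, ...], float]]:
    """All states (K, z) with their unnormalized log posterior."""
    x = np.asarray(getattr(x, "values", x), dtype=np.uint8)
    n = x.shape[0]
    if prior.k_max**n > 2_000_000:
        raise ValueError("instance too large for exhaustive enumeration")
    out = []
    for k in range(1, prior.k_max + 1):
        lp_k = prior.log_k_prior(k)
        for z in itertools.product(range(k), repeat=n):
            st = AllocationState.from_z(np.array(z), x, k)
            out.append((k, z, collapsed_joint_from_stats(st.n_k, st.s_jk, prior) + lp_k))
    return out


def exact_nonempty_k_posterior(x: np.ndarray | object, prior: MixturePrior) -> np.ndarray:
    """Exact posterior of the nonempty-component count, length K_max (index 0 = 1 cluster)."""
    states = enumerate_log_posterior(x, prior)
    logps = np.array([lp for _, _, lp in states])
    logz = logsumexp(logps)
    post = np.zeros(prior.k_max)
    for (k, z, lp) in states:
        d = len(set(z))
        post[d - 1] += np.exp(lp - logz)
    return post
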