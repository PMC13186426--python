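"""Posterior post-processing: MAP K selection, ECR relabeling, profile summaries.

A mixture posterior is invariant to permutations of component labels, so raw
draws cannot be averaged directly.  Conditional on the MAP number of nonempty
components K_map, each retained draw is aligned to a pivot allocation by the
permutation minimizing the count of disagreeing positions (the
equivalence-classes-representatives relabeling), found exactly by solving a
K_map x K_map assignment problem on the label co-occurrence matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .likelihood import MixturePrior
from .sampler import PosteriorSamples

logger = logging.getLogger(__name__)


@dataclass
class RelabeledPosterior:
    """Conditional (on K_map) posterior summaries after label alignment."""

    k_map: int
    relabeled_z_draws: np.ndarray  # (m, n) labels in 0..K_map-1
    theta_post_mean: np.ndarray  # (p, K_map)
    pi_post_mean: np.ndarray  # (K_map,)
    membership_probs: np.ndarray  # (n, K_map)

    def __post_init__(self) -> None:
        if not np.allclose(self.membership_probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if not ((self.theta_post_mean > 0) & (self.theta_post_mean < 1)).all():
            raise ValueError("theta posterior means must lie in (0, 1)")
        if abs(self.pi_post_mean.sum() - 1.0) > 1e-9:
            raise ValueError("pi posterior means must sum to 1")


def select_kmap(samples: PosteriorSamples) -> int:
    """Modal nonempty-component count; ties broken toward the smaller K."""
    if samples.k_trace.size == 0:
        raise ValueError("empty k_trace")
    counts = np.bincount(samples.k_trace)
    return int(np.argmax(counts))  # argmax returns the first (smallest) mode


def _compact_labels(z: np.ndarray) -> np.ndarray:
    """Relabel to 0..d-1 preserving sorted-unique order."""
    _, inv = np.unique(z, return_inverse=True)
    return inv.astype(np.int64)


def choose_pivot(samples: PosteriorSamples, k_map: int) -> np.ndarray:
    """The retained draw with highest log posterior among those with K_map nonempty components."""
    d = np.array([len(np.unique(z)) for z in samples.z_draws])
    eligible = np.flatnonzero(d == k_map)
    if eligible.size == 0:
        raise ValueError("no retained draw has K_map nonempty components")
    best = eligible[np.argmax(samples.logpost_trace[eligible])]
    return _compact_labels(samples.z_draws[best])


def ecr_relabel(
    z_draws: np.ndarray, pivot: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align each draw to the pivot by the disagreement-minimizing permutation.

    Draws whose nonempty-label count differs from the pivot's are excluded
    (their indices are reported).  Returns (relabeled draws with labels
    0..K_map-1, the permutations applied, indices of the draws kept).
    """
    pivot = _compact_labels(np.asarray(pivot))
    k_map = int(pivot.max()) + 1
    kept, rel, perms = [], [], []
    for idx, z in enumerate(np.asarray(z_draws)):
        zc = _compact_labels(z)
        if zc.max() + 1 != k_map:
            continue
        # agreement[a, b] = #{i : z_i = a and pivot_i = b}; maximize the matching
        agreement = np.zeros((k_map, k_map), dtype=np.int64)
        np.add.at(agreement, (zc, pivot), 1)
        rows, cols = linear_sum_assignment(-agreement)
        perm = np.empty(k_map, dtype=np.int64)
        perm[rows] = cols
        rel.append(perm[zc])
        perms.append(perm)
        kept.append(idx)
    n_dropped = len(z_draws) - len(kept)
    if n_dropped:
        logger.info("ECR: excluded %d draws with != %d nonempty components", n_dropped, k_map)
    if not kept:
        raise ValueError("no draws with the pivot's number of nonempty components")
    return np.array(rel), np.array(perms), np.array(kept)


def summarize_profiles(
    x: np.ndarray | object,
    relabeled_z_draws: np.ndarray,
    prior: MixturePrior | None = None,
    order_by_share: bool = True,
) -> RelabeledPosterior:
    """Rao-Blackwellized conditional posterior means given the relabeled draws.

    For each draw, theta_{j|k} has conditional posterior mean
    (alpha + s_jk) / (alpha + beta + n_k) and pi_k has (n_k + gamma) /
    (n + K*gamma); these are averaged over draws.  Membership probabilities
    are per-tract label frequencies.  Profiles are ordered by decreasing
    posterior share (profile 1 largest) unless ``order_by_share=False``.
    """
    prior = prior or MixturePrior()
    x = np.asarray(getattr(x, "values", x), dtype=np.int64)
    draws = np.asarray(relabeled_z_draws, dtype=np.int64)
    m, n = draws.shape
    k_map = int(draws.max()) + 1
    p = x.shape[1]

    theta_acc = np.zeros((p, k_map))
    pi_acc = np.zeros(k_map)
    member = np.zeros((n, k_map))
    for z in draws:
        onehot = np.zeros((n, k_map))
        onehot[np.arange(n), z] = 1.0
        n_k = onehot.sum(axis=0)
        s_jk = onehot.T @ x  # (K, p)
        theta_acc += ((prior.alpha + s_jk) / (prior.alpha + prior.beta + n_k[:, None])).T
        pi_acc += (n_k + prior.gamma) / (n + k_map * prior.gamma)
        member += onehot
    theta_post = theta_acc / m
    pi_post = pi_acc / m
    membership = member / m

    order = np.arange(k_map)
    if order_by_share:
        order = np.argsort(-pi_post, kind="stable")
    inv = np.empty(k_map, dtype=np.int64)
    inv[order] = np.arange(k_map)
    return RelabeledPosterior(
        k_map=k_map,
        relabeled_z_draws=inv[draws],
        theta_post_mean=theta_post[:, order],
        pi_post_mean=pi_post[order],
        membership_probs=membership[:, order],
    )


def assign_profiles(
    membership_probs: np.ndarray, tract_ids: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict]:
    """Hard assignment by row argmax (ties to the lowest profile index).

    Returns the assignment table (tract_id, profile 1..K_map, probability)
    and a summary with the median/IQR of the assignment probabilities and
    each profile's share of tracts.
    """
    probs = np.asarray(membership_probs, dtype=float)
    n, k_map = probs.shape
    if tract_ids is None:
        tract_ids = np.arange(n)
    best = probs.argmax(axis=1)  # argmax ties -> lowest index
    best_prob = probs[np.arange(n), best]
    table = pd.DataFrame(
        {
            "tract_id": np.asarray(tract_ids),
            "profile": best + 1,
            "assignment_prob": best_prob,
        }
    )
    shares = {
        int(k + 1): float((best == k).sum() / n) for k in range(k_map)
    }
    summary = {
        "k_map": int(k_map),
        "median_assignment_prob": float(np.median(best_prob)),
        "iqr_assignment_prob": float(
            np.quantile(best_prob, 0.75) - np.quantile(best_prob, 0.25)
        ),
        "profile_shares": shares,
    }
    return table, summary
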