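"""Collapsed allocation sampler over (K, z) with Metropolis-coupled chains.

State space: K in {1..K_max} labeled components (empty components allowed)
and allocations z in {0..K-1}^n.  The target is

    p(K, z | X)  propto  p(X, z | K) * Poisson_lambda(K) truncated to 1..K_max,

with pi and theta integrated out (see :mod:`.likelihood`).  Moves per sweep,
chosen from ``move_mix``: a full collapsed Gibbs reallocation pass, a block
Metropolis reallocation move, and an eject/absorb pair that changes K by
one.  Heated chain c targets the same density raised to temperatures[c];
adjacent chains attempt state swaps after every sweep.  The reported
``k_trace`` counts *nonempty* components per retained cold-chain draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

from .likelihood import AllocationState, MixturePrior, collapsed_joint_from_stats
from ._kernels import gibbs_sweep

logger = logging.getLogger(__name__)

_LOG2 = float(np.log(2.0))


@dataclass
class ChainConfig:
    """Run-length, tempering and move-mix settings for :func:`run_mc3`."""

    n_chains: int = 4
    temperatures: tuple[float, ...] | None = None
    n_iter: int = 11_000
    burn_in: int = 1_000
    thin: int = 10
    swap_attempts_per_sweep: int = 1
    move_mix: tuple[float, float, float, float] = (0.70, 0.10, 0.10, 0.10)
    eject_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.temperatures is None:
            self.temperatures = tuple(1.0 / (1.0 + 0.3 * c) for c in range(self.n_chains))
        self.temperatures = tuple(float(t) for t in self.temperatures)
        if len(self.temperatures) != self.n_chains:
            raise ValueError("temperatures length must equal n_chains")
        if self.temperatures[0] != 1.0:
            raise ValueError("temperatures[0] must be 1 (cold chain)")
        if any(not 0 < t <= 1 for t in self.temperatures):
            raise ValueError("temperatures must lie in (0, 1]")
        if abs(sum(self.move_mix) - 1.0) > 1e-9 or any(m < 0 for m in self.move_mix):
            raise ValueError("move_mix must be a probability vector over 4 move types")
        if self.n_iter < 0 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid run lengths")


@dataclass
class PosteriorSamples:
    """Retained cold-chain draws and run diagnostics."""

    z_draws: np.ndarray  # (m, n) int32 allocations (labels not yet aligned)
    k_trace: np.ndarray  # (m,) nonempty-component count
    logpost_trace: np.ndarray  # (m,) log p(X, z | K) + log p(K)
    acceptance_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.z_draws.shape[0]
        if not (self.k_trace.shape[0] == m and self.logpost_trace.shape[0] == m):
            raise ValueError("trace lengths disagree")


class _Chain:
    """One chain: allocation state at model dimension K plus its RNG."""

    def __init__(self, x: np.ndarray, prior: MixturePrior, temp: float, rng: np.random.Generator):
        self.x = x
        self.prior = prior
        self.temp = temp
        self.rng = rng
        k0 = prior.k_max
        z0 = rng.integers(k0, size=x.shape[0])
        self.state = AllocationState.from_z(z0, x, k0)

    # -- target evaluations -------------------------------------------------
    def log_joint(self) -> float:
        return collapsed_joint_from_stats(self.state.n_k, self.state.s_jk, self.prior)

    def log_post(self) -> float:
        return self.log_joint() + self.prior.log_k_prior(self.state.k)

    # -- moves ---------------------------------------------------------------
    def gibbs(self) -> None:
        unif = self.rng.random(self.x.shape[0])
        gibbs_sweep(
            self.x,
            self.state.z,
            self.state.n_k,
            self.state.s_jk,
            self.prior.gamma,
            self.prior.alpha,
            self.prior.beta,
            self.temp,
            unif,
        )


def _proposal_stats_eject(state: AllocationState, x, k0, move_rows):
    n_k = np.append(state.n_k, 0)
    s_jk = np.vstack([state.s_jk, np.zeros((1, state.s_jk.shape[1]), dtype=np.int64)])
    m = move_rows.size
    if m:
        s_moved = x[move_rows].sum(axis=0, dtype=np.int64)
        n_k[k0] -= m
        s_jk[k0] -= s_moved
        n_k[-1] = m
        s_jk[-1] = s_moved
    return n_k, s_jk


def eject_move(chain: _Chain, p_eject: float, p_absorb: float) -> bool:
    """Propose K -> K+1 by splitting a uniformly chosen component.

    Each member of the source moves to the new (last) component independently
    with probability u ~ Beta(a_e, a_e); u is marginalized out of the
    proposal density, giving the Beta-function weight in the MH ratio.
    """
    st, prior, rng = chain.state, chain.prior, chain.rng
    k = st.k
    if k >= prior.k_max:
        return False
    a_e = 1.0
    k0 = int(rng.integers(k))
    members = np.flatnonzero(st.z == k0)
    n0 = members.size
    u = rng.beta(a_e, a_e)
    mask = rng.random(n0) < u
    move_rows = members[mask]
    m = move_rows.size
    log_w = float(betaln(a_e + m, a_e + n0 - m) - betaln(a_e, a_e))

    n_k_new, s_jk_new = _proposal_stats_eject(st, chain.x, k0, move_rows)
    delta = collapsed_joint_from_stats(n_k_new, s_jk_new, prior) - chain.log_joint()
    log_acc = (
        chain.temp * (delta + np.log(prior.lam) - np.log(k + 1))
        + np.log(p_absorb)
        - np.log(p_eject)
        - log_w
    )
    if np.log(rng.random()) < log_acc:
        st.n_k, st.s_jk = n_k_new, s_jk_new
        st.z[move_rows] = k
        return True
    return False


def absorb_move(chain: _Chain, p_eject: float, p_absorb: float) -> bool:
    """Propose K -> K-1 by merging the last component into a chosen receiver."""
    st, prior, rng = chain.state, chain.prior, chain.rng
    k = st.k
    if k <= 1:
        return False
    a_e = 1.0
    r = int(rng.integers(k - 1))
    m = int(st.n_k[k - 1])
    n0_merged = int(st.n_k[r]) + m
    log_w = float(betaln(a_e + m, a_e + n0_merged - m) - betaln(a_e, a_e))

    n_k_new = st.n_k[:-1].copy()
    s_jk_new = st.s_jk[:-1].copy()
    n_k_new[r] += m
    s_jk_new[r] += st.s_jk[k - 1]
    delta = collapsed_joint_from_stats(n_k_new, s_jk_new, prior) - chain.log_joint()
    log_acc = (
        chain.temp * (delta + np.log(k) - np.log(prior.lam))
        + np.log(p_eject)
        - np.log(p_absorb)
        + log_w
    )
    if np.log(rng.random()) < log_acc:
        st.z[st.z == k - 1] = r
        st.n_k, st.s_jk = n_k_new, s_jk_new
        return True
    return False


def block_move(chain: _Chain) -> bool:
    """Metropolis block reallocation: move a random half of one component to another."""
    st, rng = chain.state, chain.rng
    k = st.k
    if k < 2:
        return False
    k1, k2 = rng.choice(k, size=2, replace=False)
    members = np.flatnonzero(st.z == k1)
    n1, n2 = int(st.n_k[k1]), int(st.n_k[k2])
    mask = rng.random(n1) < 0.5
    move_rows = members[mask]
    m = move_rows.size

    n_k_new = st.n_k.copy()
    s_jk_new = st.s_jk.copy()
    if m:
        s_moved = chain.x[move_rows].sum(axis=0, dtype=np.int64)
        n_k_new[k1] -= m
        n_k_new[k2] += m
        s_jk_new[k1] -= s_moved
        s_jk_new[k2] += s_moved
    delta = collapsed_joint_from_stats(n_k_new, s_jk_new, chain.prior) - chain.log_joint()
    log_acc = chain.temp * delta + (n1 - n2 - m) * _LOG2
    if np.log(rng.random()) < log_acc:
        st.z[move_rows] = k2
        st.n_k, st.s_jk = n_k_new, s_jk_new
        return True
    return False


def swap_step(chains: list[_Chain], rng: np.random.Generator) -> bool:
    """Attempt one state swap between a random adjacent pair of chains."""
    if len(chains) < 2:
        return False
    c = int(rng.integers(len(chains) - 1))
    lo, hi = chains[c], chains[c + 1]
    log_acc = (lo.temp - hi.temp) * (hi.log_post() - lo.log_post())
    if np.log(rng.random()) < log_acc:
        lo.state, hi.state = hi.state, lo.state
        return True
    return False


def run_mc3(
    x: np.ndarray | object,
    prior: MixturePrior | None = None,
    config: ChainConfig | None = None,
) -> PosteriorSamples:
    """Sample (K, z) from the collapsed posterior with MC^3 acceleration."""
    x = np.ascontiguousarray(getattr(x, "values", x), dtype=np.uint8)
    if x.size == 0:
        raise ValueError("X must be nonempty")
    prior = prior or MixturePrior()
    config = config or ChainConfig()

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    swap_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    chains = [
        _Chain(x, prior, config.temperatures[c], np.random.Generator(np.random.PCG64(chain_seeds[c])))
        for c in range(config.n_chains)
    ]

    p_gibbs, p_block, p_eject, p_absorb = config.move_mix
    total = config.burn_in + config.n_iter
    n_keep = config.n_iter // config.thin
    z_draws = np.empty((n_keep, x.shape[0]), dtype=np.int32)
    k_trace = np.empty(n_keep, dtype=np.int64)
    logpost_trace = np.empty(n_keep)
    attempts = {"gibbs": 0, "block": 0, "eject": 0, "absorb": 0, "swap": 0}
    accepts = {"gibbs": 0, "block": 0, "eject": 0, "absorb": 0, "swap": 0}

    kept = 0
    for t in range(total):
        for chain in chains:
            cold = chain is chains[0]
            mv = chain.rng.choice(4, p=config.move_mix)
            if mv == 0:
                chain.gibbs()
                if cold:
                    attempts["gibbs"] += 1
                    accepts["gibbs"] += 1
            elif mv == 1:
                ok = block_move(chain)
                if cold:
                    attempts["block"] += 1
                    accepts["block"] += ok
            elif mv == 2:
                ok = eject_move(chain, p_eject, p_absorb)
                if cold:
                    attempts["eject"] += 1
                    accepts["eject"] += ok
            else:
                ok = absorb_move(chain, p_eject, p_absorb)
                if cold:
                    attempts["absorb"] += 1
                    accepts["absorb"] += ok
        if config.n_chains > 1:
            for _ in range(config.swap_attempts_per_sweep):
                attempts["swap"] += 1
                accepts["swap"] += swap_step(chains, swap_rng)
        if t >= config.burn_in and (t - config.burn_in) % config.thin == 0 and kept < n_keep:
            cold_chain = chains[0]
            z_draws[kept] = cold_chain.state.z
            k_trace[kept] = cold_chain.state.n_nonempty
            logpost_trace[kept] = cold_chain.log_post()
            kept += 1
        if (t + 1) % 1000 == 0:
            logger.info(
                "sweep %d/%d, cold-chain nonempty K = %d", t + 1, total, chains[0].state.n_nonempty
            )

    report = {
        m: {"attempts": attempts[m], "rate": (accepts[m] / attempts[m] if attempts[m] else np.nan)}
        for m in attempts
    }
    return PosteriorSamples(z_draws[:kept], k_trace[:kept], logpost_trace[:kept], report)
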