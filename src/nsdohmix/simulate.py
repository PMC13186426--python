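"""Synthetic tract and patient data with known generating truth.

Two generators mirror the two data sources of the analysis: (a) tract-level
binary (and raw-proportion) indicator tables with a known mixture structure,
so that clustering can be validated against ground truth; (b) patient-level
binary care outcomes generated from a logistic model on profile membership
plus categorical covariates, so that the outcome regression can be validated
against known odds ratios.  All randomness flows from explicit integer
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import VariableCatalog, default_catalog
from .containers import BinaryDesignMatrix


@dataclass
class TrueMixture:
    """Generating mixture: component weights pi_true and emission matrix theta_true (p x K)."""

    k_true: int
    pi_true: np.ndarray
    theta_true: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.pi_true.shape != (self.k_true,):
            raise ValueError("pi_true must have length k_true")
        if abs(self.pi_true.sum() - 1.0) > 1e-12 or (self.pi_true < 0).any():
            raise ValueError("pi_true must be a probability vector summing to 1")
        if self.theta_true.ndim != 2 or self.theta_true.shape[1] != self.k_true:
            raise ValueError("theta_true must be p x k_true")
        if (self.theta_true < 0).any() or (self.theta_true > 1).any():
            raise ValueError("theta_true entries must lie in [0, 1]")

    @property
    def p(self) -> int:
        return int(self.theta_true.shape[0])


# High/low exposure patterns loosely shaped like the five observed profile
# archetypes (advantaged; disadvantaged-diverse; working-class low-education;
# diverse-secure; diverse-renter), in default-catalog column order.
_PROFILE_PATTERNS = np.array(
    [
        [0, 1, 0, 1, 1],  # renter_occupied
        [0, 1, 0, 1, 1],  # no_vehicle
        [0, 1, 0, 0, 1],  # crowding
        [0, 1, 0, 0, 0],  # no_plumbing
        [0, 1, 1, 0, 1],  # median_income (1 = below median)
        [0, 1, 1, 0, 0],  # female_head_household
        [0, 1, 1, 0, 0],  # snap_benefits
        [0, 1, 0, 0, 0],  # unemployment
        [0, 1, 1, 0, 1],  # working_class
        [0, 1, 1, 0, 1],  # no_high_school
        [0, 1, 0, 1, 1],  # limited_english
        [0, 1, 0, 0, 1],  # hispanic_latino
        [0, 1, 0, 0, 1],  # nh_black
        [0, 0, 0, 1, 1],  # nh_asian
    ],
    dtype=float,
)


def default_true_mixture(
    k_true: int = 5, p: int = 14, seed: int = 0, low: float = 0.08, high: float = 0.92
) -> TrueMixture:
    """A well-separated K=5 truth at the study dimensions (p=14).

    Exposure probabilities are ``high``/``low`` according to fixed profile
    archetype patterns; weights decay like the observed profile shares.
    """
    if k_true == 5 and p == 14:
        pattern = _PROFILE_PATTERNS
        pi = np.array([0.32, 0.25, 0.20, 0.14, 0.09])
    else:
        rng = np.random.default_rng(seed + 7919)
        pattern = (rng.random((p, k_true)) < 0.5).astype(float)
        pi = np.full(k_true, 1.0 / k_true)
    theta = low + (high - low) * pattern
    return TrueMixture(k_true=k_true, pi_true=pi / pi.sum(), theta_true=theta, seed=seed)


def simulate_mbmm(
    truth: TrueMixture, n: int, seed: int | None = None
) -> tuple[BinaryDesignMatrix, np.ndarray]:
    """Draw n tracts from the mixture; returns the binary matrix and true allocations."""
    if not isinstance(truth, TrueMixture):
        raise TypeError("truth must be a TrueMixture")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    z = rng.choice(truth.k_true, size=n, p=truth.pi_true)
    x = (rng.random((n, truth.p)) < truth.theta_true.T[z]).astype(np.uint8)
    ids = np.array([f"tract_{i:05d}" for i in range(n)])
    names = [f"var_{j:02d}" for j in range(truth.p)]
    if truth.p == 14:
        names = default_catalog().names
    return BinaryDesignMatrix(x, ids, names), z


# Skewed marginal shapes for the raw-proportion columns: the latent exposure
# indicator decides whether a tract draws from the upper or lower half of a
# right-skewed Beta marginal, so that dichotomizing at the (population)
# median recovers the indicator.
_BETA_SHAPES = (1.3, 6.0)
_INCOME_LOGMEAN, _INCOME_LOGSD = np.log(82_265.0), 0.4


def simulate_acs_like_raw(
    n: int,
    p: int,
    truth: TrueMixture,
    seed: int | None = None,
    catalog: VariableCatalog | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Raw bounded proportions (plus an income column) hiding a known mixture.

    The binary exposure matrix is drawn first from ``truth``; each raw value
    is then sampled from the half of a skewed marginal that the indicator
    selects (upper half for exposure 1 on standard variables; *lower* half
    of the income distribution for income disadvantage; zero/positive for
    incomplete plumbing).  Median-dichotomization of the output therefore
    recovers, up to tracts near the empirical median, a matrix distributed
    like ``simulate_mbmm`` output.
    """
    if p != truth.p:
        raise ValueError("p must equal the number of rows of theta_true")
    catalog = catalog or default_catalog()
    if len(catalog) != p:
        raise ValueError("catalog size must equal p")
    design, z = simulate_mbmm(truth, n, seed=seed)
    rng = np.random.default_rng((truth.seed if seed is None else seed) + 1)
    a, b = _BETA_SHAPES
    beta = stats.beta(a, b)
    u = rng.random((n, p))
    out = {}
    for j, var in enumerate(catalog):
        bit = design.values[:, j].astype(bool)
        if var.direction == "zero_threshold":
            col = np.where(bit, beta.ppf(0.5 + 0.5 * u[:, j]), 0.0)
        elif var.direction == "reversed":
            # disadvantage bit = 1 means income *below* the median
            q = np.where(bit, 0.5 * u[:, j], 0.5 + 0.5 * u[:, j])
            col = stats.lognorm(s=_INCOME_LOGSD, scale=np.exp(_INCOME_LOGMEAN)).ppf(q)
        else:
            q = np.where(bit, 0.5 + 0.5 * u[:, j], 0.5 * u[:, j])
            col = beta.ppf(q)
        out[var.name] = col
    frame = pd.DataFrame(out)
    frame.insert(0, "tract_id", design.tract_ids)
    return frame, z


DEFAULT_COVARIATE_LEVELS = {
    "year_dx": ["2015", "2016", "2017"],
    "age_group": ["<50", "50-64", ">=65"],
    "insurance": ["private", "medicare", "public", "other", "uninsured"],
    "facility_type": ["academic", "community", "specialty", "teaching"],
}


@dataclass
class TrueOutcomeModel:
    """Generating logistic model: intercept + profile offsets + covariate offsets (log-odds)."""

    intercept: float
    profile_effects: np.ndarray  # length K, reference profile (index 0) fixed at 0
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.profile_effects = np.asarray(self.profile_effects, dtype=float)
        if self.profile_effects.size and self.profile_effects[0] != 0.0:
            raise ValueError("reference profile effect must be exactly 0")
        if not np.isfinite(self.profile_effects).all() or not np.isfinite(self.intercept):
            raise ValueError("effects must be finite")
        for cov, levels in self.covariate_effects.items():
            vals = np.array(list(levels.values()), dtype=float)
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite effect for covariate {cov!r}")


def default_covariate_design(n: int, seed: int = 0) -> pd.DataFrame:
    """Random categorical covariates over the standard level sets."""
    rng = np.random.default_rng(seed)
    cols = {
        cov: rng.choice(levels, size=n)
        for cov, levels in DEFAULT_COVARIATE_LEVELS.items()
    }
    return pd.DataFrame(cols)


def simulate_patients(
    assignments: np.ndarray,
    truth: TrueOutcomeModel,
    covariate_design: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bernoulli outcomes from the logistic truth, given profiles and covariates.

    ``assignments`` holds 1-based profile labels; covariate levels must
    belong to the level sets keyed by ``truth.covariate_effects`` (levels
    missing from the effect map contribute 0, i.e. are reference levels).
    """
    profiles = np.asarray(assignments, dtype=np.int64)
    k = truth.profile_effects.size
    if profiles.min(initial=1) < 1 or profiles.max(initial=1) > k:
        raise ValueError("profile assignments outside 1..K")
    n = profiles.size
    if len(covariate_design) != n:
        raise ValueError("covariate_design length must match assignments")
    eta = truth.intercept + truth.profile_effects[profiles - 1]
    for cov, effects in truth.covariate_effects.items():
        if cov not in covariate_design.columns:
            raise KeyError(f"covariate {cov!r} missing from design")
        levels = covariate_design[cov].astype(str)
        known = set(DEFAULT_COVARIATE_LEVELS.get(cov, levels.unique()))
        bad = set(levels.unique()) - known - set(effects)
        if bad:
            raise ValueError(f"unknown level(s) {sorted(bad)} for covariate {cov!r}")
        eta = eta + levels.map(lambda s: effects.get(s, 0.0)).to_numpy()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    prob = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng.random(n) < prob).astype(np.int64)
    out = covariate_design.copy()
    out.insert(0, "profile", profiles)
    out.insert(0, "outcome", outcome)
    return out
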