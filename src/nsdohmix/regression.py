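"""Bayesian logistic regression of a binary care outcome on profile membership.

The model is a standard logistic regression with dummy-coded profile and
covariate terms under independent Normal(0, scale^2) priors (weakly
informative; they regularize sparse profile-by-covariate cells).  The exact
posterior is sampled by random-walk Metropolis whose proposal covariance is
the inverse Hessian of the log posterior at its mode, scaled by 2.38^2/d.
Because all predictors are categorical, rows are collapsed to unique
covariate patterns with binomial likelihood contributions, which makes each
posterior evaluation cheap regardless of the patient count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


def _collapse(design: np.ndarray, outcomes: np.ndarray):
    patterns, inverse = np.unique(design, axis=0, return_inverse=True)
    trials = np.bincount(inverse, minlength=len(patterns)).astype(float)
    successes = np.bincount(inverse, weights=outcomes, minlength=len(patterns))
    return patterns, trials, successes


def _log_posterior_parts(patterns, trials, successes, prior_var):
    def neg_log_post(beta):
        eta = patterns @ beta
        # log(1 + e^eta) computed stably
        log1pexp = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
        ll = successes @ eta - trials @ log1pexp
        lp = -0.5 * np.sum(beta**2 / prior_var)
        return -(ll + lp)

    def grad(beta):
        eta = patterns @ beta
        mu = trials / (1.0 + np.exp(-eta))
        return -(patterns.T @ (successes - mu) - beta / prior_var)

    def hess(beta):
        eta = patterns @ beta
        pr = 1.0 / (1.0 + np.exp(-eta))
        w = trials * pr * (1.0 - pr)
        return patterns.T @ (patterns * w[:, None]) + np.diag(1.0 / prior_var)

    return neg_log_post, grad, hess


def build_design(
    records: pd.DataFrame,
    reference_profile: int = 1,
    reference_levels: dict[str, str] | None = None,
    covariates: tuple[str, ...] = ("year_dx", "age_group", "insurance", "facility_type"),
) -> tuple[np.ndarray, list[str]]:
    """Full-rank dummy coding with an intercept and stated reference levels.

    Profile ``reference_profile`` and each covariate's reference level are
    omitted; a covariate observed at a single level contributes no columns.
    """
    reference_levels = reference_levels or {}
    cols = [np.ones(len(records))]
    names = ["intercept"]

    profiles = records["profile"].astype(int)
    prof_levels = sorted(profiles.unique())
    if reference_profile not in prof_levels:
        raise ValueError(f"reference profile {reference_profile} absent from data")
    for lev in prof_levels:
        if lev == reference_profile:
            continue
        cols.append((profiles == lev).to_numpy(float))
        names.append(f"profile[{lev}]")

    for cov in covariates:
        if cov not in records.columns:
            raise KeyError(f"covariate {cov!r} missing from records")
        values = records[cov].astype(str)
        levels = sorted(values.unique())
        ref = reference_levels.get(cov, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from covariate {cov!r}")
        for lev in levels:
            if lev == ref:
                continue
            cols.append((values == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


@dataclass
class RegressionResult:
    """Posterior draws, OR table and sampler diagnostics."""

    term_names: list[str]
    coefficient_draws: np.ndarray  # (chains, draws, d)
    or_table: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    map_estimate: np.ndarray | None = None

    @property
    def flat_draws(self) -> np.ndarray:
        return self.coefficient_draws.reshape(-1, self.coefficient_draws.shape[-1])

    def summary(self) -> str:
        lines = [
            "Bayesian logistic regression",
            "=" * 46,
            f"terms: {len(self.term_names)}   "
            f"draws: {self.flat_draws.shape[0]} "
            f"({self.coefficient_draws.shape[0]} chains)",
            f"mean acceptance rate: {self.diagnostics.get('acceptance_rate', float('nan')):.2f}",
            "",
            self.or_table.round(3).to_string(index=False),
        ]
        return "\n".join(lines)


def fit_bayes_logistic(
    design: np.ndarray,
    outcomes: np.ndarray,
    term_names: list[str] | None = None,
    prior_scale: float = 2.5,
    intercept_scale: float = 10.0,
    draws: int = 5_000,
    warmup: int = 1_000,
    chains: int = 4,
    seed: int = 0,
) -> RegressionResult:
    """Sample the exact posterior of the logistic coefficients.

    Priors are independent Normal(0, prior_scale^2) on indicator terms and
    Normal(0, intercept_scale^2) on the intercept (the first column when its
    name is ``intercept``).
    """
    design = np.asarray(design, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if not np.isin(outcomes, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    n, d = design.shape
    if term_names is None:
        term_names = [f"b{j}" for j in range(d)]
    if n < d:
        import warnings

        warnings.warn("fewer observations than design columns; posterior is prior-dominated")

    prior_var = np.full(d, prior_scale**2)
    if term_names[0] == "intercept":
        prior_var[0] = intercept_scale**2

    patterns, trials, successes = _collapse(design, outcomes)
    neg_log_post, grad, hess = _log_posterior_parts(patterns, trials, successes, prior_var)

    opt = optimize.minimize(neg_log_post, np.zeros(d), jac=grad, method="BFGS")
    beta_map = optimize.minimize(neg_log_post, opt.x, jac=grad, method="Newton-CG", hess=hess).x
    h = hess(beta_map)
    cov = np.linalg.inv(h) * (2.38**2 / d)
    chol = np.linalg.cholesky(cov)

    rng_master = np.random.SeedSequence(seed)
    all_draws = np.empty((chains, draws, d))
    acc_rates = []
    for c, child in enumerate(rng_master.spawn(chains)):
        rng = np.random.default_rng(child)
        beta = beta_map + chol @ rng.standard_normal(d)
        lp = -neg_log_post(beta)
        n_acc = 0
        total = warmup + draws
        for t in range(total):
            prop = beta + chol @ rng.standard_normal(d)
            lp_prop = -neg_log_post(prop)
            if np.log(rng.random()) < lp_prop - lp:
                beta, lp = prop, lp_prop
                n_acc += 1
            if t >= warmup:
                all_draws[c, t - warmup] = beta
        acc_rates.append(n_acc / total)

    flat = all_draws.reshape(-1, d)
    rows = []
    for j, name in enumerate(term_names):
        if name == "intercept":
            continue
        ors = np.exp(flat[:, j])
        rows.append(
            {
                "term": name,
                "or_mean": ors.mean(),
                "or_2.5%": np.quantile(ors, 0.025),
                "or_97.5%": np.quantile(ors, 0.975),
            }
        )
    or_table = pd.DataFrame(rows)

    try:
        import arviz as az

        ess = az.ess(az.convert_to_dataset(all_draws, group="posterior"))
        ess_by_term = {
            term_names[j]: float(np.asarray(ess["x"])[j]) for j in range(d)
        }
    except Exception:  # pragma: no cover - diagnostics only
        ess_by_term = {}

    diagnostics = {
        "acceptance_rate": float(np.mean(acc_rates)),
        "acceptance_rates": [float(a) for a in acc_rates],
        "ess": ess_by_term,
    }
    return RegressionResult(term_names, all_draws, or_table, diagnostics, beta_map)


def crude_or_from_table(
    contingency: pd.DataFrame | np.ndarray,
    ref: int = 1,
    continuity: float | None = None,
) -> pd.Series:
    """Crude per-profile odds ratios from a profile x outcome count table.

    ``contingency`` rows are profiles (1-based index or in order) and columns
    are (not-optimal, optimal) counts.  OR_k = (opt_k / not_k) /
    (opt_ref / not_ref).  Zero cells raise unless ``continuity`` (e.g. 0.5)
    is given, in which case it is added to every cell.
    """
    if isinstance(contingency, pd.DataFrame):
        counts = contingency.to_numpy(dtype=float)
        index = list(contingency.index)
    else:
        counts = np.asarray(contingency, dtype=float)
        index = list(range(1, counts.shape[0] + 1))
    if counts.shape[1] != 2:
        raise ValueError("contingency must have two columns: (not optimal, optimal)")
    if (counts == 0).any():
        if continuity is None:
            raise ValueError("zero cell in contingency table; pass continuity=0.5")
        counts = counts + continuity
    ref_pos = index.index(ref)
    odds = counts[:, 1] / counts[:, 0]
    return pd.Series(odds / odds[ref_pos], index=index, name="crude_or")


class BayesianLogit:
    """Model object: binary outcome regressed on profile + categorical covariates."""

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        term_names: list[str] | None = None,
        prior_scale: float = 2.5,
        intercept_scale: float = 10.0,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.term_names = term_names or [f"b{j}" for j in range(self.exog.shape[1])]
        self.prior_scale = prior_scale
        self.intercept_scale = intercept_scale

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        outcome: str = "outcome",
        reference_profile: int = 1,
        reference_levels: dict[str, str] | None = None,
        covariates: tuple[str, ...] = ("year_dx", "age_group", "insurance", "facility_type"),
        **kwargs,
    ) -> "BayesianLogit":
        design, names = build_design(records, reference_profile, reference_levels, covariates)
        return cls(records[outcome].to_numpy(), design, names, **kwargs)

    def map_estimate(self) -> np.ndarray:
        """Posterior mode (penalized MLE) of the coefficient vector."""
        d = self.exog.shape[1]
        prior_var = np.full(d, self.prior_scale**2)
        if self.term_names[0] == "intercept":
            prior_var[0] = self.intercept_scale**2
        patterns, trials, successes = _collapse(self.exog, self.endog)
        neg_log_post, grad, hess = _log_posterior_parts(patterns, trials, successes, prior_var)
        opt = optimize.minimize(neg_log_post, np.zeros(d), jac=grad, method="BFGS")
        return optimize.minimize(neg_log_post, opt.x, jac=grad, method="Newton-CG", hess=hess).x

    def fit(self, draws: int = 5_000, warmup: int = 1_000, chains: int = 4, seed: int = 0) -> RegressionResult:
        return fit_bayes_logistic(
            self.exog,
            self.endog,
            self.term_names,
            prior_scale=self.prior_scale,
            intercept_scale=self.intercept_scale,
            draws=draws,
            warmup=warmup,
            chains=chains,
            seed=seed,
        )
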