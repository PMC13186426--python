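"""Model/Results front end for the Bernoulli mixture profile analysis.

``BernoulliMixtureModel`` holds the binary design matrix and the prior;
``fit`` runs the MC^3 allocation sampler, selects K_map, resolves label
switching and returns a ``BernoulliMixtureResults`` carrying the posterior
summaries, hard profile assignments and diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import BinaryDesignMatrix
from .likelihood import MixturePrior
from .postprocess import (
    RelabeledPosterior,
    assign_profiles,
    choose_pivot,
    ecr_relabel,
    select_kmap,
    summarize_profiles,
)
from .sampler import ChainConfig, PosteriorSamples, run_mc3


class BernoulliMixtureModel:
    """Multivariate Bernoulli mixture with an unknown number of components."""

    def __init__(self, design: BinaryDesignMatrix, prior: MixturePrior | None = None):
        self.design = design
        self.prior = prior or MixturePrior()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        id_col: str = "tract_id",
        prior: MixturePrior | None = None,
    ) -> "BernoulliMixtureModel":
        return cls(BinaryDesignMatrix.from_frame(frame, id_col=id_col), prior=prior)

    def fit(
        self, config: ChainConfig | None = None, **config_kwargs
    ) -> "BernoulliMixtureResults":
        if config is None:
            config = ChainConfig(**config_kwargs)
        elif config_kwargs:
            raise TypeError("pass either a ChainConfig or keyword overrides, not both")
        samples = run_mc3(self.design.values, self.prior, config)
        k_map = select_kmap(samples)
        pivot = choose_pivot(samples, k_map)
        relabeled, _, kept = ecr_relabel(samples.z_draws, pivot)
        posterior = summarize_profiles(self.design.values, relabeled, self.prior)
        return BernoulliMixtureResults(self, config, samples, k_map, posterior, kept)


class BernoulliMixtureResults:
    """Fitted profile posterior: K_map, aligned draws, summaries, assignments."""

    def __init__(
        self,
        model: BernoulliMixtureModel,
        config: ChainConfig,
        samples: PosteriorSamples,
        k_map: int,
        posterior: RelabeledPosterior,
        kept_draws: np.ndarray,
    ):
        self.model = model
        self.config = config
        self.samples = samples
        self.k_map = k_map
        self.posterior = posterior
        self.kept_draws = kept_draws
        self.assignments, self.assignment_summary = assign_profiles(
            posterior.membership_probs, model.design.tract_ids
        )

    @property
    def theta_post_mean(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.posterior.theta_post_mean,
            index=self.model.design.variable_names,
            columns=[f"profile_{k + 1}" for k in range(self.k_map)],
        )

    @property
    def pi_post_mean(self) -> pd.Series:
        return pd.Series(
            self.posterior.pi_post_mean,
            index=[f"profile_{k + 1}" for k in range(self.k_map)],
        )

    def summary(self) -> str:
        s = self.assignment_summary
        lines = [
            "Bernoulli mixture profile model",
            "=" * 46,
            f"tracts: {self.model.design.n}   indicators: {self.model.design.p}",
            f"retained draws: {len(self.samples.k_trace)} "
            f"(conditional on K_map: {len(self.kept_draws)})",
            f"K_map (modal nonempty components): {self.k_map}",
            f"median assignment probability: {s['median_assignment_prob']:.3f} "
            f"(IQR {s['iqr_assignment_prob']:.3f})",
            "profile shares: "
            + ", ".join(f"{k}: {v:.1%}" for k, v in s["profile_shares"].items()),
            "",
            "posterior mean P(high exposure | profile):",
            self.theta_post_mean.round(3).to_string(),
        ]
        return "\n".join(lines)

    def plot_profiles(self, ax=None):
        """Bar panel of posterior exposure probabilities by profile."""
        import matplotlib.pyplot as plt

        theta = self.theta_post_mean
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        theta.plot.bar(ax=ax, width=0.85)
        ax.set_ylabel("posterior P(high exposure)")
        ax.set_ylim(0, 1)
        ax.legend(title=None, fontsize=8)
        return ax
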