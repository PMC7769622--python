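"""Scikit-learn style estimator facade over the model, sampler and scores.

``LocalGlobalAttentionModel`` is the package's primary user surface: a
generative model of saccadic scan paths on a static saliency map that is
*fitted* with the Pólya-Gamma Gibbs / HMC sampler, *samples* new scan
paths, and *scores* held-out paths by their predictive information gain.
It follows the sklearn estimator contract (``get_params`` /
``set_params``, fitted attributes with a trailing underscore, idempotent
``fit``) and composes with sklearn model-selection utilities.
"""

from __future__ import annotations

from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fixations import validate_fixation_table
from .inference import GibbsConfig, PosteriorSamples, run_gibbs
from .maps import scanpath_loglik
from .metrics import ScoreReport, score_paths
from .params import Hyperparams, ModelParams, VARIANTS
from .saliency import SaliencyMap
from .simulate import sample_cohort, sample_scanpath

__all__ = ["LocalGlobalAttentionModel"]


def _as_map_dict(saliency) -> Dict[object, SaliencyMap]:
    if isinstance(saliency, SaliencyMap):
        return {0: saliency}
    return dict(saliency)


class LocalGlobalAttentionModel(BaseEstimator):
    """Two-state (local/global attention) generative scan-path model.

    Parameters
    ----------
    variant : str
        One of ``full``, ``local_choice``, ``fixed_choice``,
        ``local_saliency``, ``saliency_baseline``.
    hyper : Hyperparams, optional
        Prior hyperparameters; a wide data-dependent default is derived
        when omitted.
    n_iter, n_burn, n_chains, thin, hmc_steps, step_size, target_accept :
        Sampler settings, forwarded to the Gibbs engine.
    random_state : int, optional
        Master seed of the fit.

    Attributes
    ----------
    posterior_ : PosteriorSamples
        Post-burn-in draws with diagnostics.
    params_ : ModelParams
        Posterior-mean parameter configuration.
    rhat_ : dict
        Split-chain R-hat per parameter.
    converged_ : bool
        Whether all R-hat values fall below the configured threshold.
    n_saccades_ : int
        Number of modeled saccades (fixations with index >= 3).
    """

    def __init__(
        self,
        variant: str = "full",
        hyper: Optional[Hyperparams] = None,
        n_iter: int = 1500,
        n_burn: int = 500,
        n_chains: int = 4,
        thin: int = 1,
        hmc_steps: int = 10,
        step_size: float = 0.05,
        target_accept: float = 0.65,
        rhat_threshold: float = 1.1,
        random_state: Optional[int] = None,
    ):
        self.variant = variant
        self.hyper = hyper
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.n_chains = n_chains
        self.thin = thin
        self.hmc_steps = hmc_steps
        self.step_size = step_size
        self.target_accept = target_accept
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _gibbs_config(self) -> GibbsConfig:
        return GibbsConfig(
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            n_chains=self.n_chains,
            thin=self.thin,
            hmc_steps=self.hmc_steps,
            step_size=self.step_size,
            target_accept=self.target_accept,
            rhat_threshold=self.rhat_threshold,
            seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, saliency) -> "LocalGlobalAttentionModel":
        """Fit the model to one observer's fixation table.

        ``X`` is a fixation table (six named columns); ``saliency`` a
        SaliencyMap (single image) or a dict image_id -> SaliencyMap.
        """
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        maps = _as_map_dict(saliency)
        if X is not None and len(X) > 0:
            X = validate_fixation_table(X, shape=next(iter(maps.values())).shape)
        self.posterior_ = run_gibbs(
            X, maps, self.variant, self.hyper, self._gibbs_config()
        )
        self.params_ = self.posterior_.mean_params()
        self.rhat_ = self.posterior_.rhat()
        self.converged_ = self.posterior_.converged(self.rhat_threshold)
        data_n = 0 if X is None else len(X)
        self.n_saccades_ = sum(
            max(0, n - 2)
            for n in (
                X.groupby(["subject_id", "image_id", "trial_id"]).size()
                if data_n
                else []
            )
        )
        return self

    # ------------------------------------------------------------------

    def _params_or_default(self) -> ModelParams:
        if hasattr(self, "posterior_"):
            return self.params_
        return ModelParams(variant=self.variant)

    def sample(
        self,
        saliency,
        n_fix: int = 35,
        n_subjects: int = 1,
        random_state=None,
    ) -> pd.DataFrame:
        """Simulate one scan path per (subject, image) at the fitted
        (posterior mean) parameters; usable unfitted with the defaults."""
        maps = _as_map_dict(saliency)
        params = self._params_or_default()
        table, _ = sample_cohort(
            maps,
            {s: params for s in range(n_subjects)},
            n_fix,
            random_state,
        )
        return table

    def sample_path(self, saliency: SaliencyMap, n_fix: int = 35, random_state=None):
        return sample_scanpath(
            saliency,
            self._params_or_default(),
            n_fix,
            np.random.default_rng(random_state),
        )

    def log_likelihood(self, X: pd.DataFrame, saliency) -> float:
        """Total log-likelihood (nats) of a fixation table under the
        fitted posterior-mean parameters."""
        from .fixations import table_to_paths

        maps = _as_map_dict(saliency)
        params = self._params_or_default()
        total = 0.0
        for (s, img, tr), path in table_to_paths(X).items():
            ll, _, _ = scanpath_loglik(path, params, maps[img])
            total += ll
        return total

    def score(self, X: pd.DataFrame, saliency, random_state=None) -> float:
        """Mean predictive information gain (bit/fix) over a uniform
        baseline; larger is better (sklearn score convention)."""
        return self.score_report(X, saliency, random_state=random_state).ig

    def score_report(
        self, X: pd.DataFrame, saliency, n_negatives_per_positive: int = 10,
        random_state=None,
    ) -> ScoreReport:
        from .fixations import table_to_paths

        maps = _as_map_dict(saliency)
        return score_paths(
            table_to_paths(X),
            self._params_or_default(),
            maps,
            n_negatives_per_positive=n_negatives_per_positive,
            rng=random_state,
        )
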