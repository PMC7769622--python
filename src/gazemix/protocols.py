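"""Canned study protocols: simulation-based checks of the inference and
of the model's behavioural signatures.

These drive the package's validation workflows:

- **parameter recovery** — simulate one observer's worth of data from
  known parameters, fit with dispersed multi-start chains, and check that
  every true value falls inside its central credible interval;
- **prior recovery** — fit an empty dataset and compare the draws with
  the priors (a standard sampler null check);
- **amplitude structure** — the two-length-scale signature of the full
  model: local-tagged saccades are stochastically shorter than
  global-tagged ones and successive amplitudes are anti-correlated at
  lag 1, neither of which the single-scale variant shows;
- **model comparison** — by-image cross-validated information gain of the
  full model against its simplified competitors on data generated by the
  full model;
- **saliency recovery** — the aggregate fixation density of
  saliency-baseline simulations reproduces the input map.

The default study conditions (grid geometry, cohort sizes, path lengths,
generating parameters) are fixed here once; docs/methods.md discusses the
choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .fixations import table_to_paths
from .inference import GibbsConfig, run_gibbs
from .metrics import amplitude_autocorrelation, crossvalidate
from .params import Hyperparams, ModelParams
from .saliency import SaliencyMap, synthetic_saliency
from .simulate import sample_scanpath, synthetic_dataset

__all__ = [
    "RECOVERY_TRUTH",
    "RECOVERY_HYPER",
    "recovery_replicate",
    "prior_recovery",
    "amplitude_structure",
    "model_comparison_replicate",
    "saliency_recovery_pvalue",
    "merged_chisquare",
]

#: generating parameters of the recovery protocol, in px^2 on the default
#: 48x48 study grid at 2 px/degree: local sd 3 px (1.5 deg), global sd
#: ~14 px (7 deg), gate slope 3 on the saliency-ratio scale, offset 1
RECOVERY_TRUTH = ModelParams(eps_x=9.0, eps_y=9.0, xi_x=200.0, xi_y=200.0,
                             b=3.0, s_o=1.0)

#: wide, weakly-informative priors whose modes avoid the generating
#: values (IG(1.5, .) modes 12 and 100 px^2 against truths 9 and 200;
#: Gaussian modes 0 against 3 and 1); the small shape keeps the priors
#: nearly flat over a decade so coverage is driven by the likelihood
RECOVERY_HYPER = Hyperparams(
    alpha_eps=1.5, beta_eps=30.0, alpha_xi=1.5, beta_xi=250.0,
    mu_b=0.0, sigma_b=5.0, mu_so=0.0, sigma_so=5.0,
)


@dataclass
class RecoveryResult:
    truth: Dict[str, float]
    posterior_mean: Dict[str, float]
    ci: Dict[str, Tuple[float, float]]
    truth_in_ci: Dict[str, bool]
    rhat: Dict[str, float]
    accept_rate: np.ndarray

    @property
    def all_covered(self) -> bool:
        return all(self.truth_in_ci.values())

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def recovery_replicate(
    seed: int,
    truth: ModelParams = RECOVERY_TRUTH,
    hyper: Hyperparams = RECOVERY_HYPER,
    n_images: int = 30,
    n_fix: int = 24,
    shape: Tuple[int, int] = (48, 48),
    config: Optional[GibbsConfig] = None,
    ci_level: float = 0.9,
) -> RecoveryResult:
    """One parameter-recovery replicate: simulate -> fit -> compare.

    One simulated observer: 30 images (one path each) of 24 fixations,
    i.e. ~660 modeled saccades, on 48x48 grids at 2 px/degree.
    """
    ds = synthetic_dataset(
        truth, n_subjects=1, n_images=n_images, n_fix=n_fix, shape=shape,
        n_modes=3, seed=seed, px_per_degree=2.0, map_floor=0.3,
    )
    config = config or GibbsConfig(
        n_iter=600, n_burn=250, n_chains=3, hmc_steps=5, seed=seed + 1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        post = run_gibbs(ds.table, ds.saliency_maps, truth.variant, hyper, config)
    ci = post.credible_interval(ci_level)
    td = truth.to_dict()
    return RecoveryResult(
        truth={k: td[k] for k in post.param_names},
        posterior_mean=post.posterior_mean(),
        ci=ci,
        truth_in_ci={k: ci[k][0] <= td[k] <= ci[k][1] for k in post.param_names},
        rhat=post.rhat(),
        accept_rate=post.accept_rate,
    )


def prior_recovery(
    hyper: Optional[Hyperparams] = None,
    n_draws: int = 5000,
    thin: int = 5,
    seed: int = 0,
) -> Dict[str, float]:
    """KS p-values of empty-dataset posterior draws against the priors."""
    hyper = hyper or Hyperparams()
    burn = 500
    cfg = GibbsConfig(
        n_iter=burn + n_draws * thin, n_burn=burn, n_chains=1, thin=thin,
        hmc_steps=10, seed=seed,
    )
    post = run_gibbs(None, {}, "full", hyper, cfg)
    out = {}
    for name, draws in post.draws.items():
        x = draws.ravel()
        if name in ("eps_x", "eps_y"):
            dist = stats.invgamma(hyper.alpha_eps, scale=hyper.beta_eps)
        elif name in ("xi_x", "xi_y"):
            dist = stats.invgamma(hyper.alpha_xi, scale=hyper.beta_xi)
        elif name == "b":
            dist = stats.norm(hyper.mu_b, hyper.sigma_b)
        else:
            dist = stats.norm(hyper.mu_so, hyper.sigma_so)
        out[name] = float(stats.kstest(x, dist.cdf).pvalue)
    return out


@dataclass
class AmplitudeStructure:
    local_amplitudes: np.ndarray
    global_amplitudes: np.ndarray
    mode_separation_p: float  # Mann-Whitney, local < global
    lag1_per_cohort: np.ndarray
    lag1_sign_p: float  # binomial sign test for negative lag-1


def amplitude_structure(
    params: ModelParams,
    n_cohorts: int = 20,
    n_paths: int = 12,
    n_fix: int = 20,
    shape: Tuple[int, int] = (48, 48),
    seed: int = 0,
) -> AmplitudeStructure:
    """Two-length-scale signature of a variant's simulations.

    Pools tagged saccade amplitudes over all cohorts and computes the
    per-cohort mean lag-1 amplitude autocorrelation.
    """
    ss = np.random.SeedSequence(seed)
    loc_amp: List[float] = []
    glob_amp: List[float] = []
    lag1 = np.empty(n_cohorts)
    for c, cohort_seed in enumerate(ss.spawn(n_cohorts)):
        child = cohort_seed.spawn(n_paths + 1)
        smap = synthetic_saliency(shape, 3, child[0])
        paths = {}
        for i in range(n_paths):
            rng = np.random.default_rng(child[i + 1])
            path = sample_scanpath(smap, params, n_fix, rng)
            paths[("s", i, 1)] = path
            if path.tags is not None:
                amps = path.amplitudes()
                for t in range(2, len(path)):
                    if path.tags[t] == "local":
                        loc_amp.append(amps[t - 1])
                    elif path.tags[t] == "global":
                        glob_amp.append(amps[t - 1])
        lag1[c] = amplitude_autocorrelation(paths, max_lag=1)[1]
    if loc_amp and glob_amp:
        mw = stats.mannwhitneyu(loc_amp, glob_amp, alternative="less")
        mode_p = float(mw.pvalue)
    else:
        mode_p = float("nan")
    n_neg = int((lag1 < 0).sum())
    sign_p = float(stats.binomtest(n_neg, n_cohorts, 0.5, alternative="greater").pvalue)
    return AmplitudeStructure(
        np.asarray(loc_amp), np.asarray(glob_amp), mode_p, lag1, sign_p
    )


def model_comparison_replicate(
    seed: int,
    truth: ModelParams = RECOVERY_TRUTH,
    n_subjects: int = 2,
    n_images: int = 30,
    n_fix: int = 12,
    shape: Tuple[int, int] = (32, 32),
    k: int = 5,
    config: Optional[GibbsConfig] = None,
    variants: Tuple[str, ...] = (
        "full", "local_choice", "fixed_choice", "local_saliency"
    ),
) -> Dict[str, float]:
    """Cross-validated test information gain (bit/fix) per variant on data
    generated by the full model; higher is better."""
    # smaller length scales keep the repulsion zone well inside this grid
    gen = truth.replace(eps_x=4.0, eps_y=4.0, xi_x=90.0, xi_y=90.0)
    ds = synthetic_dataset(
        gen, n_subjects=n_subjects, n_images=n_images, n_fix=n_fix,
        shape=shape, n_modes=3, seed=seed, px_per_degree=2.0,
    )
    config = config or GibbsConfig(
        n_iter=160, n_burn=70, n_chains=1, hmc_steps=5, seed=seed
    )
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for variant in variants:
            rep = crossvalidate(
                ds.table, ds.saliency_maps, variant=variant, k=k,
                config=config, rng=seed + 17,
            )
            out[variant] = float(rep["ig"].mean())
    return out


def merged_chisquare(counts: np.ndarray, probs: np.ndarray, min_expected: float = 5.0):
    """Chi-square goodness of fit after merging low-expectation cells."""
    n = counts.sum()
    order = np.argsort(probs)[::-1]
    obs, exp = [], []
    acc_o = acc_e = 0.0
    for i in order:
        acc_o += counts[i]
        acc_e += n * probs[i]
        if acc_e >= min_expected:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        obs[-1] += acc_o
        exp[-1] += acc_e
    exp = np.asarray(exp) * (np.sum(obs) / np.sum(exp))
    return stats.chisquare(obs, exp)


def saliency_recovery_pvalue(
    n_fixations: int = 100_000,
    shape: Tuple[int, int] = (24, 24),
    seed: int = 0,
) -> float:
    """Chi-square GOF p-value of the aggregate fixation density of
    saliency-baseline simulations against the generating map."""
    ss = np.random.SeedSequence(seed)
    s_map, s_path = ss.spawn(2)
    smap = synthetic_saliency(shape, 3, s_map)
    params = ModelParams(variant="saliency_baseline")
    rng = np.random.default_rng(s_path)
    n_fix_per_path = 50
    counts = np.zeros(smap.n_pixels)
    for _ in range(n_fixations // n_fix_per_path):
        path = sample_scanpath(smap, params, n_fix_per_path, rng, record_tags=False)
        idx = path.ys.astype(int) * smap.width + path.xs.astype(int)
        np.add.at(counts, idx, 1.0)
    return float(merged_chisquare(counts, smap.values.ravel()).pvalue)
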