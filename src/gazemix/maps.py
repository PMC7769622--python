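"""Step distributions and scan-path likelihoods of the attention model.

The model is a second-order Markov process over fixation locations on a
discrete pixel grid.  Given the previous fixation ``z_{t-1}``, the next
fixation is drawn either from a *local* map (a diagonal Gaussian around
``z_{t-1}``, normalized within the image) or from a *global* map (the
saliency map modulated by a broad Gaussian, with the local Gaussian
subtracted and clamped at zero to create a repulsion zone around the
current fixation).  A logistic link on the saliency ratio of the two most
recent fixations gates the choice between the two modes:

    p(z_t | z_{t-1}, z_{t-2}) = rho_t p_local(z_t) + (1 - rho_t) p_global(z_t)
    rho_t = sigmoid( b (s(z_{t-1}) / s(z_{t-2}) - s_o) )

Simplified variants replace the ratio by the raw saliency value
(``local_choice``), by a constant probability (``fixed_choice``), drop the
mixture altogether (``local_saliency``), or sample every fixation straight
from the saliency map (``saliency_baseline``).

All Gaussian kernels are evaluated un-truncated at pixel centers and the
resulting maps renormalized within the image, which is equivalent to
truncation followed by renormalization.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Tuple

import numpy as np
from scipy.special import expit

from .fixations import ScanPath
from .params import (
    DegenerateGlobalMapError,
    LOGLIK_FLOOR,
    MIXTURE_VARIANTS,
    ModelParams,
    RATIO_FLOOR,
)
from .saliency import SaliencyMap

__all__ = [
    "local_map",
    "global_map",
    "local_saliency_map",
    "saliency_baseline_map",
    "rho_link",
    "rho_link_local_choice",
    "rho_for_step",
    "step_probability",
    "step_distribution",
    "scanpath_loglik",
    "StepBreakdown",
]

LOG2E = np.log2(np.e)


def _gauss_1d(n: int, center: float, var: float) -> np.ndarray:
    """exp(-(k - center)^2 / (2 var)) at integer pixel centers k = 0..n-1."""
    k = np.arange(n, dtype=float)
    return np.exp(-((k - center) ** 2) / (2.0 * var))


def _raw_gauss_2d(shape: Tuple[int, int], z_prev, var_x: float, var_y: float
                  ) -> np.ndarray:
    """Bivariate diagonal Gaussian *density* n(z; z_prev, diag(var)) at
    pixel centers, including the 1/(2 pi sqrt(vx vy)) normalizing constant."""
    h, w = shape
    x0, y0 = float(z_prev[0]), float(z_prev[1])
    gx = _gauss_1d(w, x0, var_x)
    gy = _gauss_1d(h, y0, var_y)
    const = 1.0 / (2.0 * np.pi * np.sqrt(var_x * var_y))
    return const * np.outer(gy, gx)


def _check_in_grid(z, shape) -> None:
    h, w = shape
    if not (0 <= z[0] < w and 0 <= z[1] < h):
        raise ValueError(f"location {z} outside the {h}x{w} grid")


def local_map(z_prev, params: ModelParams, shape: Tuple[int, int]) -> np.ndarray:
    """Local-attention step distribution: Gaussian around the current
    fixation with covariance diag(eps), renormalized over the image."""
    _check_in_grid(z_prev, shape)
    values = _raw_gauss_2d(shape, z_prev, params.eps_x, params.eps_y)
    return values / values.sum()


def global_map(
    z_prev,
    params: ModelParams,
    saliency: SaliencyMap,
    return_unnormalized: bool = False,
):
    """Global-attention step distribution.

    Per pixel ``max(s(z) n(z; z_prev, xi) - n(z; z_prev, eps), 0)``,
    renormalized over the image.  The subtracted local kernel carves a
    repulsion zone around the current fixation so that global saccades
    have a minimum length.
    """
    _check_in_grid(z_prev, saliency.shape)
    n_xi = _raw_gauss_2d(saliency.shape, z_prev, params.xi_x, params.xi_y)
    n_eps = _raw_gauss_2d(saliency.shape, z_prev, params.eps_x, params.eps_y)
    raw = np.maximum(saliency.values * n_xi - n_eps, 0.0)
    total = raw.sum()
    if total <= 0.0:
        raise DegenerateGlobalMapError(
            "global attention map is identically zero after clamping"
        )
    if return_unnormalized:
        return raw / total, raw, total
    return raw / total


def local_saliency_map(
    z_prev, params: ModelParams, saliency: SaliencyMap
) -> np.ndarray:
    """Single-mode variant: saliency modulated by a Gaussian of covariance
    diag(xi) around the current fixation, renormalized."""
    _check_in_grid(z_prev, saliency.shape)
    n_xi = _raw_gauss_2d(saliency.shape, z_prev, params.xi_x, params.xi_y)
    raw = saliency.values * n_xi
    return raw / raw.sum()


def saliency_baseline_map(saliency: SaliencyMap) -> np.ndarray:
    """History-independent baseline: each fixation sampled from the map."""
    return saliency.values


def rho_link(s_prev: float, s_prev2: float, params: ModelParams) -> float:
    """Gating probability of the full model: sigmoid of the scaled
    saliency ratio of the two most recent fixations."""
    ratio = s_prev / max(s_prev2, RATIO_FLOOR)
    return float(expit(params.b * (ratio - params.s_o)))


def rho_link_local_choice(s_prev: float, params: ModelParams) -> float:
    """Gating probability of the local_choice variant: sigmoid of the
    scaled saliency value at the current fixation."""
    return float(expit(params.b * (s_prev - params.s_o)))


def rho_for_step(z_prev, z_prev2, params: ModelParams, saliency: SaliencyMap) -> float:
    """Per-variant gating probability given the two most recent fixations."""
    if params.variant == "fixed_choice":
        return float(params.rho_fixed)
    s_prev = float(saliency.value_at(int(z_prev[0]), int(z_prev[1])))
    if params.variant == "local_choice":
        return rho_link_local_choice(s_prev, params)
    s_prev2 = float(saliency.value_at(int(z_prev2[0]), int(z_prev2[1])))
    return rho_link(s_prev, s_prev2, params)


class StepBreakdown(NamedTuple):
    prob: float
    rho: float
    p_local: float
    p_global: float


def step_probability(
    z_t, z_prev, z_prev2, params: ModelParams, saliency: SaliencyMap
) -> StepBreakdown:
    """Probability of observing fixation ``z_t`` after ``z_prev, z_prev2``
    under a mixture variant, with the mixture breakdown."""
    if params.variant not in MIXTURE_VARIANTS:
        raise ValueError(
            f"step_probability applies to mixture variants, not {params.variant!r}"
        )
    xt, yt = int(z_t[0]), int(z_t[1])
    _check_in_grid(z_t, saliency.shape)
    rho = rho_for_step(z_prev, z_prev2, params, saliency)
    p_loc = float(local_map(z_prev, params, saliency.shape)[yt, xt])
    p_glob = float(global_map(z_prev, params, saliency)[yt, xt])
    return StepBreakdown(rho * p_loc + (1.0 - rho) * p_glob, rho, p_loc, p_glob)


def step_distribution(
    z_prev, z_prev2, params: ModelParams, saliency: SaliencyMap
) -> np.ndarray:
    """Full conditional distribution of the next fixation over all pixels
    (the model's per-step prediction map), for any variant."""
    if params.variant == "saliency_baseline":
        return saliency_baseline_map(saliency)
    if params.variant == "local_saliency":
        return local_saliency_map(z_prev, params, saliency)
    rho = rho_for_step(z_prev, z_prev2, params, saliency)
    p_loc = local_map(z_prev, params, saliency.shape)
    p_glob = global_map(z_prev, params, saliency)
    return rho * p_loc + (1.0 - rho) * p_glob


def scanpath_loglik(
    path: ScanPath,
    params: ModelParams,
    saliency: SaliencyMap,
    base: str = "e",
):
    """Log-likelihood of a scan path under one model variant.

    ``log p(Z | Theta) = log s(z_1) + log s(z_2) +
    sum_{t>=3} log p(z_t | z_{t-1}, z_{t-2})``.  Per-step probabilities are
    floored at 1e-300 before the log for numerical stability; steps whose
    raw probability was exactly zero are flagged in the returned mask.

    Returns
    -------
    total : float
    per_step : ndarray of length T (per-fixation log-probabilities)
    zero_mask : boolean ndarray, True where the raw probability was 0
    """
    path.check_in_grid(saliency.shape)
    t_len = len(path)
    probs = np.empty(t_len)
    xs = path.xs.astype(int)
    ys = path.ys.astype(int)
    probs[0] = saliency.values[ys[0], xs[0]]
    probs[1] = saliency.values[ys[1], xs[1]]
    for t in range(2, t_len):
        z_t = (xs[t], ys[t])
        z_prev = (xs[t - 1], ys[t - 1])
        z_prev2 = (xs[t - 2], ys[t - 2])
        dist = step_distribution(z_prev, z_prev2, params, saliency)
        probs[t] = dist[ys[t], xs[t]]
    zero_mask = probs == 0.0
    per_step = np.log(np.maximum(probs, LOGLIK_FLOOR))
    if base == "2":
        per_step = per_step * LOG2E
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return float(per_step.sum()), per_step, zero_mask
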