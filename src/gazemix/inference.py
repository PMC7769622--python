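"""Bayesian inference for the attention model: Gibbs with HMC-within-Gibbs.

The augmented posterior is sampled by cycling

  1. per-saccade mode indicators  gamma_t ~ Bernoulli(posterior odds of the
     local vs global component),
  2. Polya-Gamma auxiliaries      w_t ~ PG(1, f_t) at the current link value,
  3. link slope                   b   ~ exact Gaussian full conditional,
  4. link offset                  s_o ~ exact Gaussian full conditional,
  5. covariance scales            (eps, xi) ~ one Hamiltonian Monte Carlo
     transition targeting their log conditional (Inverse-Gamma priors,
     log-space coordinates with the Jacobian term, xi > eps enforced by
     rejection).

The PG augmentation makes the logistic gate conditionally Gaussian in
(b, s_o): with design value x_t (the saliency ratio minus s_o for the
slope update, and analogous linear forms for the offset), the full
conditionals follow the standard completion of squares,

  prec_b = 1/sigma_b^2 + sum w_t x_t^2,
  mean_b = prec_b^-1 (mu_b/sigma_b^2 + sum (gamma_t - 1/2) x_t).

Simplified variants reuse the same machinery: ``local_choice`` swaps the
ratio for the raw saliency value, ``fixed_choice`` replaces steps 2-4 by a
conjugate Beta update of its constant gate, and ``local_saliency`` keeps
only the HMC update of xi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import (
    DegenerateGlobalMapError,
    Hyperparams,
    LOGLIK_FLOOR,
    MIXTURE_VARIANTS,
    ModelParams,
    RATIO_FLOOR,
)
from ._kernels import HAVE_NUMBA, global_sums, localsal_sums
from .polya import sample_pg
from .saliency import SaliencyMap

__all__ = [
    "SaccadeData",
    "GibbsConfig",
    "PosteriorSamples",
    "gamma_probabilities",
    "sample_gamma",
    "b_conditional",
    "sample_b",
    "s_o_conditional",
    "sample_s_o",
    "sample_rho_fixed",
    "hmc_transition",
    "run_gibbs",
]

_NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


class SaccadeData:
    """Per-subject dataset flattened to modeled-saccade arrays.

    For every fixation with index t >= 3 in a trial this stores the
    displacement from the previous fixation, the previous location (the
    Gaussian centers), the saliency at the target, and the link design
    value (saliency ratio, or raw saliency for ``local_choice``), plus the
    image each saccade belongs to.  All maps must share one grid.
    """

    def __init__(
        self,
        table: Optional[pd.DataFrame],
        saliency_maps: Dict[object, SaliencyMap],
        variant: str = "full",
    ):
        self.variant = variant
        shapes = {m.shape for m in saliency_maps.values()}
        if len(shapes) > 1:
            raise ValueError("all saliency maps must share one grid geometry")
        self.shape = shapes.pop() if shapes else (2, 2)
        h, w = self.shape
        image_ids = list(saliency_maps.keys())
        self.maps = np.stack(
            [saliency_maps[i].values for i in image_ids]
        ) if image_ids else np.zeros((0, h, w))
        img_pos = {im: k for k, im in enumerate(image_ids)}

        dx, dy, xp, yp, xt, yt, s_t, design, img = [], [], [], [], [], [], [], [], []
        n_paths = 0
        if table is not None and len(table) > 0:
            for (_, image_id, _), sub in table.groupby(
                ["subject_id", "image_id", "trial_id"], sort=False
            ):
                if image_id not in img_pos:
                    raise ValueError(f"no saliency map for image {image_id!r}")
                sub = sub.sort_values("fixation_index")
                x = sub["x"].to_numpy(dtype=float)
                y = sub["y"].to_numpy(dtype=float)
                if len(x) < 3:
                    continue
                n_paths += 1
                sv = saliency_maps[image_id].value_at(x.astype(int), y.astype(int))
                for t in range(2, len(x)):
                    dx.append(x[t] - x[t - 1])
                    dy.append(y[t] - y[t - 1])
                    xp.append(x[t - 1])
                    yp.append(y[t - 1])
                    xt.append(int(x[t]))
                    yt.append(int(y[t]))
                    s_t.append(sv[t])
                    if variant == "local_choice":
                        design.append(sv[t - 1])
                    else:
                        design.append(sv[t - 1] / max(sv[t - 2], RATIO_FLOOR))
                    img.append(img_pos[image_id])
        self.n_paths = n_paths
        self.dx = np.asarray(dx, dtype=float)
        self.dy = np.asarray(dy, dtype=float)
        self.xp = np.asarray(xp, dtype=float)
        self.yp = np.asarray(yp, dtype=float)
        self.xt = np.asarray(xt, dtype=int)
        self.yt = np.asarray(yt, dtype=int)
        self.s_t = np.asarray(s_t, dtype=float)
        self.design = np.asarray(design, dtype=float)
        self.img = np.asarray(img, dtype=int)
        self.n = len(self.dx)
        self.xs_grid = np.arange(w, dtype=float)
        self.ys_grid = np.arange(h, dtype=float)
        # parameter-independent distance tables, computed once
        self.dxg2 = (self.xs_grid[None, :] - self.xp[:, None]) ** 2  # (n, W)
        self.dyg2 = (self.ys_grid[None, :] - self.yp[:, None]) ** 2  # (n, H)
        self.dxt2 = self.dx**2
        self.dyt2 = self.dy**2
        # unique Gaussian centers for the separable local normalizers
        self._ux, self._ux_inv = np.unique(self.xp, return_inverse=True)
        self._uy, self._uy_inv = np.unique(self.yp, return_inverse=True)
        self._ux_d2 = (self.xs_grid[None, :] - self._ux[:, None]) ** 2
        self._uy_d2 = (self.ys_grid[None, :] - self._uy[:, None]) ** 2

    # -- local component ----------------------------------------------------

    def _axis_normalizers(self, axis: str, var: float, with_grad: bool):
        """Sum over one axis grid of exp(-(k-c)^2/2v) for the cached unique
        centers, mapped back to saccade order; optionally with d/dv terms."""
        d2 = self._ux_d2 if axis == "x" else self._uy_d2
        inv = self._ux_inv if axis == "x" else self._uy_inv
        e = np.exp(-d2 / (2.0 * var))
        s = e.sum(axis=1)
        if not with_grad:
            return s[inv], None
        ds = (e * d2).sum(axis=1) / (2.0 * var**2)
        return s[inv], ds[inv]

    def local_values(self, eps_x: float, eps_y: float,
                     idx: Optional[np.ndarray] = None) -> np.ndarray:
        """p_local(z_t | z_{t-1}) at the observed targets."""
        if idx is None:
            idx = slice(None)
        sx, _ = self._axis_normalizers("x", eps_x, False)
        sy, _ = self._axis_normalizers("y", eps_y, False)
        num = np.exp(
            -self.dxt2[idx] / (2.0 * eps_x) - self.dyt2[idx] / (2.0 * eps_y)
        )
        return num / (sx[idx] * sy[idx])

    def local_logp_and_grad(self, eps_x: float, eps_y: float, idx: np.ndarray,
                            with_grad: bool = True):
        """Sum of log p_local over the selected saccades and its gradient
        with respect to (eps_x, eps_y)."""
        if len(idx) == 0:
            return 0.0, np.zeros(2)
        sx_all, dsx_all = self._axis_normalizers("x", eps_x, with_grad)
        sy_all, dsy_all = self._axis_normalizers("y", eps_y, with_grad)
        sx, sy = sx_all[idx], sy_all[idx]
        dsx = dsx_all[idx] if with_grad else None
        dsy = dsy_all[idx] if with_grad else None
        sdx2 = float(self.dxt2[idx].sum())
        sdy2 = float(self.dyt2[idx].sum())
        logp = (
            -sdx2 / (2.0 * eps_x)
            - sdy2 / (2.0 * eps_y)
            - np.log(sx).sum()
            - np.log(sy).sum()
        )
        if not with_grad:
            return float(logp), None
        gx = sdx2 / (2.0 * eps_x**2) - (dsx / sx).sum()
        gy = sdy2 / (2.0 * eps_y**2) - (dsy / sy).sum()
        return float(logp), np.array([gx, gy])

    # -- global component ---------------------------------------------------

    def _global_pieces(self, eps_x, eps_y, xi_x, xi_y, idx, with_grad):
        """Numerators, normalizers and (optionally) their parameter
        gradients for the clamped global map at the selected saccades.
        One batched pass over all selected saccades; each indexes its own
        image's raster."""
        c_xi = 1.0 / (2.0 * np.pi * np.sqrt(xi_x * xi_y))
        c_ep = 1.0 / (2.0 * np.pi * np.sqrt(eps_x * eps_y))
        dxg2 = self.dxg2[idx]  # (m, W)
        dyg2 = self.dyg2[idx]  # (m, H)
        ex_xi = np.exp(-dxg2 / (2.0 * xi_x))
        ey_xi = np.exp(-dyg2 / (2.0 * xi_y))
        ex_ep = np.exp(-dxg2 / (2.0 * eps_x))
        ey_ep = np.exp(-dyg2 / (2.0 * eps_y))
        img_idx = self.img[idx]
        if HAVE_NUMBA:
            U, sa, sb, sa_dx2, sa_dy2, sb_dx2, sb_dy2 = global_sums(
                self.maps, img_idx, ex_xi, ey_xi, ex_ep, ey_ep, dxg2, dyg2,
                c_xi, c_ep, with_grad,
            )
        else:
            s_sel = self.maps[img_idx]  # (m, H, W)
            a = (c_xi * s_sel) * (ey_xi[:, :, None] * ex_xi[:, None, :])
            bmat = (c_ep * ey_ep[:, :, None]) * ex_ep[:, None, :]
            act = (a - bmat) > 0.0
            a_act = np.where(act, a, 0.0)
            b_act = np.where(act, bmat, 0.0)
            U = (a_act - b_act).sum(axis=(1, 2))
            if with_grad:
                sa = a_act.sum(axis=(1, 2))
                sb = b_act.sum(axis=(1, 2))
                sa_dx2 = np.einsum("mhw,mw->m", a_act, dxg2)
                sa_dy2 = np.einsum("mhw,mh->m", a_act, dyg2)
                sb_dx2 = np.einsum("mhw,mw->m", b_act, dxg2)
                sb_dy2 = np.einsum("mhw,mh->m", b_act, dyg2)
        # numerator at the observed target
        dxt = self.dx[idx]
        dyt = self.dy[idx]
        a_t = self.s_t[idx] * c_xi * np.exp(
            -dxt**2 / (2.0 * xi_x) - dyt**2 / (2.0 * xi_y)
        )
        b_t = c_ep * np.exp(-dxt**2 / (2.0 * eps_x) - dyt**2 / (2.0 * eps_y))
        u_t = a_t - b_t
        if not with_grad:
            return u_t, U, None, None
        grads_U = np.stack(
            [
                -(sb_dx2 / (2.0 * eps_x**2) - sb / (2.0 * eps_x)),
                -(sb_dy2 / (2.0 * eps_y**2) - sb / (2.0 * eps_y)),
                sa_dx2 / (2.0 * xi_x**2) - sa / (2.0 * xi_x),
                sa_dy2 / (2.0 * xi_y**2) - sa / (2.0 * xi_y),
            ],
            axis=1,
        )
        grads_u = np.stack(
            [
                -b_t * (dxt**2 / (2.0 * eps_x**2) - 1.0 / (2.0 * eps_x)),
                -b_t * (dyt**2 / (2.0 * eps_y**2) - 1.0 / (2.0 * eps_y)),
                a_t * (dxt**2 / (2.0 * xi_x**2) - 1.0 / (2.0 * xi_x)),
                a_t * (dyt**2 / (2.0 * xi_y**2) - 1.0 / (2.0 * xi_y)),
            ],
            axis=1,
        )
        return u_t, U, grads_u, grads_U

    def global_values(self, eps_x, eps_y, xi_x, xi_y,
                      idx: Optional[np.ndarray] = None) -> np.ndarray:
        """p_global(z_t | z_{t-1}) at the observed targets (0 inside the
        repulsion zone).  Raises on a degenerate (all-clamped) map."""
        if idx is None:
            idx = np.arange(self.n)
        u_t, U, _, _ = self._global_pieces(eps_x, eps_y, xi_x, xi_y, idx, False)
        if np.any(U <= 0.0):
            raise DegenerateGlobalMapError(
                "global attention map is identically zero after clamping"
            )
        return np.maximum(u_t, 0.0) / U

    def global_support_ok(self, eps_x, eps_y, xi_x, xi_y, idx: np.ndarray) -> bool:
        """True when the clamped global map keeps positive mass at every
        selected saccade's origin (the model's validity region)."""
        if len(idx) == 0:
            return True
        _, U, _, _ = self._global_pieces(eps_x, eps_y, xi_x, xi_y, idx, False)
        return bool(np.all(U > 0.0))

    def global_logp_and_grad(self, eps_x, eps_y, xi_x, xi_y, idx: np.ndarray,
                             with_grad: bool = True):
        """Sum of log p_global over the selected saccades and its gradient
        with respect to (eps_x, eps_y, xi_x, xi_y); -inf if any observed
        target lies in the clamped region or a map degenerates."""
        if len(idx) == 0:
            return 0.0, np.zeros(4)
        u_t, U, g_u, g_U = self._global_pieces(
            eps_x, eps_y, xi_x, xi_y, idx, with_grad
        )
        if np.any(U <= 0.0) or np.any(u_t <= 0.0):
            return _NEG_INF, None
        logp = float(np.log(u_t).sum() - np.log(U).sum())
        if not with_grad:
            return logp, None
        grad = (g_u / u_t[:, None] - g_U / U[:, None]).sum(axis=0)
        return logp, grad

    # -- local-saliency component -------------------------------------------

    def localsal_logp_and_grad(self, xi_x, xi_y, with_grad: bool = True):
        """Sum over all saccades of log [s(z_t) n_xi(z_t) / sum s n_xi] and
        its gradient with respect to (xi_x, xi_y)."""
        if self.n == 0:
            return 0.0, np.zeros(2)
        dxg2, dyg2 = self.dxg2, self.dyg2
        ex = np.exp(-dxg2 / (2.0 * xi_x))
        ey = np.exp(-dyg2 / (2.0 * xi_y))
        if HAVE_NUMBA:
            U, sa_dx2, sa_dy2 = localsal_sums(
                self.maps, self.img, ex, ey, dxg2, dyg2, with_grad
            )
        else:
            a = self.maps[self.img] * (ey[:, :, None] * ex[:, None, :])
            U = a.sum(axis=(1, 2))
            if with_grad:
                sa_dx2 = np.einsum("mhw,mw->m", a, dxg2)
                sa_dy2 = np.einsum("mhw,mh->m", a, dyg2)
        dxt, dyt = self.dx, self.dy
        log_num = np.log(self.s_t) - dxt**2 / (2.0 * xi_x) - dyt**2 / (2.0 * xi_y)
        logp = float(log_num.sum() - np.log(U).sum())
        if not with_grad:
            return logp, None
        grad = np.array(
            [
                ((dxt**2).sum() - (sa_dx2 / U).sum()) / (2.0 * xi_x**2),
                ((dyt**2).sum() - (sa_dy2 / U).sum()) / (2.0 * xi_y**2),
            ]
        )
        return logp, grad


# ---------------------------------------------------------------------------
# exact conditionals
# ---------------------------------------------------------------------------


def gamma_probabilities(rho, p_local, p_global) -> np.ndarray:
    """Posterior probability that each saccade followed the local mode:
    rho p_local / (rho p_local + (1 - rho) p_global)."""
    rho = np.asarray(rho, dtype=float)
    num = rho * np.asarray(p_local, dtype=float)
    den = num + (1.0 - rho) * np.asarray(p_global, dtype=float)
    if np.any(den <= 0.0):
        raise ValueError(
            "both mixture components have zero probability at an observed "
            "fixation; data and parameters are inconsistent"
        )
    return num / den


def sample_gamma(rho, p_local, p_global, rng: np.random.Generator) -> np.ndarray:
    prob = gamma_probabilities(rho, p_local, p_global)
    return (rng.random(prob.shape) < prob).astype(int)


def b_conditional(x, gamma, w, hyper: Hyperparams) -> Tuple[float, float]:
    """Gaussian full conditional of the link slope b.

    ``x`` is the per-saccade design value (ratio - s_o, or value - s_o)."""
    x = np.asarray(x, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    w = np.asarray(w, dtype=float)
    prec = 1.0 / hyper.sigma_b**2 + float((w * x**2).sum())
    mean = (hyper.mu_b / hyper.sigma_b**2 + float(((gamma - 0.5) * x).sum())) / prec
    return mean, 1.0 / np.sqrt(prec)


def sample_b(x, gamma, w, hyper: Hyperparams, rng: np.random.Generator) -> float:
    mean, sd = b_conditional(x, gamma, w, hyper)
    return float(rng.normal(mean, sd))


def s_o_conditional(design, gamma, w, b: float, hyper: Hyperparams
                    ) -> Tuple[float, float]:
    """Gaussian full conditional of the link offset s_o.

    With f_t = b (r_t - s_o) the design coefficient of s_o is -b and the
    per-saccade offset is b r_t, giving
    prec = 1/sigma^2 + b^2 sum w, mean = prec^-1 (mu/sigma^2
    - b sum(gamma - 1/2) + b^2 sum w r)."""
    design = np.asarray(design, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    w = np.asarray(w, dtype=float)
    prec = 1.0 / hyper.sigma_so**2 + b**2 * float(w.sum())
    mean = (
        hyper.mu_so / hyper.sigma_so**2
        - b * float((gamma - 0.5).sum())
        + b**2 * float((w * design).sum())
    ) / prec
    return mean, 1.0 / np.sqrt(prec)


def sample_s_o(design, gamma, w, b, hyper: Hyperparams,
               rng: np.random.Generator) -> float:
    mean, sd = s_o_conditional(design, gamma, w, b, hyper)
    return float(rng.normal(mean, sd))


def sample_rho_fixed(gamma, hyper: Hyperparams, rng: np.random.Generator) -> float:
    """Conjugate Beta update of the fixed_choice gate."""
    gamma = np.asarray(gamma)
    n1 = int(gamma.sum()) if gamma.size else 0
    n0 = int(gamma.size - n1)
    return float(rng.beta(hyper.beta_a + n1, hyper.beta_b + n0))


# ---------------------------------------------------------------------------
# HMC
# ---------------------------------------------------------------------------


def hmc_transition(
    logpost_and_grad: Callable[[np.ndarray], Tuple[float, Optional[np.ndarray]]],
    u0: np.ndarray,
    step_size: float,
    n_leapfrog: int,
    rng: np.random.Generator,
    lp0: Optional[float] = None,
    grad0: Optional[np.ndarray] = None,
):
    """One Hamiltonian Monte Carlo transition with identity mass matrix.

    Returns ``(u, accepted, accept_prob, lp, grad)``; proposals with
    non-finite log-density or gradient are rejected.
    """
    if lp0 is None or grad0 is None:
        lp0, grad0 = logpost_and_grad(u0)
    if not np.isfinite(lp0):
        raise ValueError("HMC started from a zero-density state")
    p = rng.standard_normal(u0.shape)
    h0 = lp0 - 0.5 * float(p @ p)
    u = u0.copy()
    grad = grad0
    p = p + 0.5 * step_size * grad
    diverged = False
    for i in range(n_leapfrog):
        u = u + step_size * p
        lp, grad = logpost_and_grad(u)
        if not np.isfinite(lp) or grad is None or not np.all(np.isfinite(grad)):
            diverged = True
            break
        p = p + (0.5 if i == n_leapfrog - 1 else 1.0) * step_size * grad
    if diverged:
        return u0, False, 0.0, lp0, grad0
    h1 = lp - 0.5 * float(p @ p)
    accept_prob = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
    if rng.random() < accept_prob:
        return u, True, accept_prob, lp, grad
    return u0, False, accept_prob, lp0, grad0


class _DualAveraging:
    """Nesterov dual averaging of the HMC step size toward a target
    acceptance rate during burn-in."""

    def __init__(self, step0: float, target: float = 0.65, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.h_bar = 0.0
        self.log_step_bar = np.log(step0)
        self.log_step = np.log(step0)
        self.m = 0

    def update(self, accept_prob: float) -> float:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_step = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        eta = self.m ** (-self.kappa)
        self.log_step_bar = eta * self.log_step + (1.0 - eta) * self.log_step_bar
        return float(np.exp(self.log_step))

    @property
    def final_step(self) -> float:
        return float(np.exp(self.log_step_bar))


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class GibbsConfig:
    """Sampler settings (all configurable; see docs/methods.md)."""

    n_iter: int = 1500
    n_burn: int = 500
    n_chains: int = 4
    thin: int = 1
    hmc_steps: int = 10
    step_size: float = 0.05
    target_accept: float = 0.65
    adapt_step_size: bool = True
    link_sweeps: int = 5  # extra (w, b, s_o) scans per iteration: the link
    # parameters are strongly coupled and these scans are grid-free, so
    # re-scanning them accelerates mixing at negligible cost
    marginal_moves: int = 3  # random-walk Metropolis proposals per iteration
    # on the scales, targeting the tag-marginalized mixture posterior; the
    # tag-conditional HMC update alone can trap a chain in a metastable
    # (scales, tags) configuration, which these moves escape
    marginal_step: float = 0.25  # log-space proposal sd of those moves
    rhat_threshold: float = 1.1
    seed: Optional[int] = None


@dataclass
class PosteriorSamples:
    """Post-burn-in draws of Theta with sampler diagnostics."""

    draws: Dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    log_post: np.ndarray  # (n_chains, n_kept), up to an additive constant
    accept_rate: np.ndarray  # per chain, HMC acceptance after burn-in
    variant: str
    hyper: Hyperparams
    seed: Optional[int]
    final_gamma: Optional[np.ndarray] = None

    @property
    def param_names(self) -> List[str]:
        return list(self.draws.keys())

    def rhat(self) -> Dict[str, float]:
        return {k: _split_rhat(v) for k, v in self.draws.items()}

    def ess(self) -> Dict[str, float]:
        import arviz as az

        return {
            k: float(az.ess(_to_az(v))["x"].values) for k, v in self.draws.items()
        }

    def converged(self, threshold: float = 1.1) -> bool:
        return all(r < threshold for r in self.rhat().values())

    def credible_interval(self, level: float = 0.9) -> Dict[str, Tuple[float, float]]:
        lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
        return {
            k: (float(np.quantile(v, lo)), float(np.quantile(v, hi)))
            for k, v in self.draws.items()
        }

    def posterior_mean(self) -> Dict[str, float]:
        return {k: float(v.mean()) for k, v in self.draws.items()}

    def last_states(self) -> List[Dict[str, float]]:
        """Final parameter state of each chain (for resuming/extending)."""
        n_chains = next(iter(self.draws.values())).shape[0]
        return [
            {k: float(v[c, -1]) for k, v in self.draws.items()}
            for c in range(n_chains)
        ]

    def mean_params(self) -> ModelParams:
        m = self.posterior_mean()
        kw = dict(variant=self.variant)
        for name in ("eps_x", "eps_y", "xi_x", "xi_y", "b", "s_o", "rho_fixed"):
            if name in m:
                kw[name] = m[name]
        if self.variant in MIXTURE_VARIANTS:
            # guard the xi > eps support against pathological summaries
            kw["xi_x"] = max(kw["xi_x"], 1.001 * kw["eps_x"])
            kw["xi_y"] = max(kw["xi_y"], 1.001 * kw["eps_y"])
        return ModelParams(**kw)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        n_chains = next(iter(self.draws.values())).shape[0]
        for c in range(n_chains):
            d = {"chain": c, "iteration": np.arange(self.log_post.shape[1])}
            for k, v in self.draws.items():
                d[k] = v[c]
            d["log_posterior"] = self.log_post[c]
            frames.append(pd.DataFrame(d))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        rh = self.rhat()
        ci = self.credible_interval(0.9)
        rows = []
        for k, v in self.draws.items():
            rows.append(
                {
                    "parameter": k,
                    "mean": float(v.mean()),
                    "sd": float(v.std()),
                    "ci5": ci[k][0],
                    "ci95": ci[k][1],
                    "rhat": rh[k],
                }
            )
        return pd.DataFrame(rows)


def _to_az(arr: np.ndarray):
    import arviz as az

    return az.convert_to_dataset(arr[:, :, None].transpose(0, 1, 2)[..., 0])


def _split_rhat(arr: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (rank-normalization-free
    classic form; chains split in half to detect within-chain drift)."""
    chains = []
    for c in arr:
        half = len(c) // 2
        if half < 2:
            return np.nan
        chains.append(c[:half])
        chains.append(c[half : 2 * half])
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    means = x.mean(axis=1)
    variances = x.var(axis=1, ddof=1)
    w = variances.mean()
    bvar = n * means.var(ddof=1)
    if w <= 0.0:
        return 1.0
    var_hat = (n - 1) / n * w + bvar / n
    return float(np.sqrt(var_hat / w))


def _prior_scale_draw(hyper: Hyperparams, rng: np.random.Generator, kind: str) -> float:
    alpha = hyper.alpha_eps if kind == "eps" else hyper.alpha_xi
    beta = hyper.beta_eps if kind == "eps" else hyper.beta_xi
    return float(beta / rng.gamma(alpha))  # IG(alpha, beta) via inverse Gamma


def _ig_logpdf_logspace(u: float, alpha: float, beta: float) -> float:
    # IG(theta; a, b) with theta = exp(u), including the Jacobian theta
    return -alpha * u - beta * np.exp(-u)


def _ig_grad_logspace(u: float, alpha: float, beta: float) -> float:
    return -alpha + beta * np.exp(-u)


class _GibbsEngine:
    """One-subject Gibbs sampler over (gamma, w, b, s_o, eps, xi)."""

    def __init__(self, data: SaccadeData, variant: str, hyper: Hyperparams,
                 config: GibbsConfig):
        if variant == "saliency_baseline":
            raise ValueError("the saliency baseline has no parameters to infer")
        self.data = data
        self.variant = variant
        self.hyper = hyper
        self.config = config
        if variant == "local_saliency":
            self.scale_names = ["xi_x", "xi_y"]
        else:
            self.scale_names = ["eps_x", "eps_y", "xi_x", "xi_y"]
        self.link_names = (
            ["b", "s_o"] if variant in ("full", "local_choice")
            else (["rho_fixed"] if variant == "fixed_choice" else [])
        )

    # ---- conditional log-target of the scales (given gamma) ----

    def _scale_target(self, gamma: Optional[np.ndarray]):
        data, hyper = self.data, self.hyper

        if self.variant == "local_saliency":
            def logpost(u: np.ndarray):
                if np.any(np.abs(u) > 300.0):  # far outside any plausible scale
                    return _NEG_INF, None
                xi_x, xi_y = np.exp(u)
                lp_prior = (
                    _ig_logpdf_logspace(u[0], hyper.alpha_xi, hyper.beta_xi)
                    + _ig_logpdf_logspace(u[1], hyper.alpha_xi, hyper.beta_xi)
                )
                g_prior = np.array(
                    [
                        _ig_grad_logspace(u[0], hyper.alpha_xi, hyper.beta_xi),
                        _ig_grad_logspace(u[1], hyper.alpha_xi, hyper.beta_xi),
                    ]
                )
                ll, g = data.localsal_logp_and_grad(xi_x, xi_y)
                if not np.isfinite(ll):
                    return _NEG_INF, None
                return ll + lp_prior, np.array([xi_x, xi_y]) * g + g_prior

            return logpost

        local_idx = np.where(gamma == 1)[0] if gamma is not None else np.array([], int)
        global_idx = np.where(gamma == 0)[0] if gamma is not None else np.array([], int)

        def logpost(u: np.ndarray):
            if np.any(np.abs(u) > 300.0):  # far outside any plausible scale
                return _NEG_INF, None
            eps_x, eps_y, xi_x, xi_y = np.exp(u)
            if not (xi_x > eps_x and xi_y > eps_y):
                return _NEG_INF, None
            lp = (
                _ig_logpdf_logspace(u[0], self.hyper.alpha_eps, self.hyper.beta_eps)
                + _ig_logpdf_logspace(u[1], self.hyper.alpha_eps, self.hyper.beta_eps)
                + _ig_logpdf_logspace(u[2], self.hyper.alpha_xi, self.hyper.beta_xi)
                + _ig_logpdf_logspace(u[3], self.hyper.alpha_xi, self.hyper.beta_xi)
            )
            grad = np.array(
                [
                    _ig_grad_logspace(u[0], self.hyper.alpha_eps, self.hyper.beta_eps),
                    _ig_grad_logspace(u[1], self.hyper.alpha_eps, self.hyper.beta_eps),
                    _ig_grad_logspace(u[2], self.hyper.alpha_xi, self.hyper.beta_xi),
                    _ig_grad_logspace(u[3], self.hyper.alpha_xi, self.hyper.beta_xi),
                ]
            )
            ll_loc, g_loc = data.local_logp_and_grad(eps_x, eps_y, local_idx)
            if not np.isfinite(ll_loc):
                return _NEG_INF, None
            # one batched pass over every saccade: the mixture must remain
            # well defined at every observed origin (support check), and the
            # global-tagged subset contributes log-density and gradient
            if data.n > 0:
                u_t, U, g_u, g_U = data._global_pieces(
                    eps_x, eps_y, xi_x, xi_y, np.arange(data.n), True
                )
                if np.any(U <= 0.0):
                    return _NEG_INF, None
                gi = global_idx
                if len(gi) and np.any(u_t[gi] <= 0.0):
                    return _NEG_INF, None
                if len(gi):
                    ll_glob = float(np.log(u_t[gi]).sum() - np.log(U[gi]).sum())
                    g_glob = (
                        g_u[gi] / u_t[gi, None] - g_U[gi] / U[gi, None]
                    ).sum(axis=0)
                else:
                    ll_glob, g_glob = 0.0, np.zeros(4)
            else:
                ll_glob, g_glob = 0.0, np.zeros(4)
            theta = np.array([eps_x, eps_y, xi_x, xi_y])
            g_theta = np.zeros(4)
            g_theta[:2] += g_loc
            g_theta += g_glob
            return ll_loc + ll_glob + lp, theta * g_theta + grad

        return logpost

    # ---- per-sweep mixture quantities ----

    def _mixture_values(self, params: Dict[str, float]):
        data = self.data
        p_loc = data.local_values(params["eps_x"], params["eps_y"])
        p_glob = data.global_values(
            params["eps_x"], params["eps_y"], params["xi_x"], params["xi_y"]
        )
        if self.variant == "fixed_choice":
            rho = np.full(data.n, params["rho_fixed"])
        else:
            from scipy.special import expit

            rho = expit(params["b"] * (data.design - params["s_o"]))
        return rho, p_loc, p_glob

    def _log_posterior(self, params: Dict[str, float], rho, p_loc, p_glob) -> float:
        """Marginal (gamma-integrated) log posterior up to the constant
        initial-fixation terms."""
        mix = rho * p_loc + (1.0 - rho) * p_glob
        ll = float(np.log(np.maximum(mix, LOGLIK_FLOOR)).sum())
        h = self.hyper
        lp = 0.0
        if self.variant != "local_saliency":
            for nm in ("eps_x", "eps_y"):
                th = params[nm]
                lp += -(h.alpha_eps + 1) * np.log(th) - h.beta_eps / th
        for nm in ("xi_x", "xi_y"):
            th = params[nm]
            lp += -(h.alpha_xi + 1) * np.log(th) - h.beta_xi / th
        if self.variant in ("full", "local_choice"):
            lp += -0.5 * ((params["b"] - h.mu_b) / h.sigma_b) ** 2
            lp += -0.5 * ((params["s_o"] - h.mu_so) / h.sigma_so) ** 2
        elif self.variant == "fixed_choice":
            r = min(max(params["rho_fixed"], 1e-12), 1 - 1e-12)
            lp += (h.beta_a - 1) * np.log(r) + (h.beta_b - 1) * np.log(1 - r)
        return ll + lp

    def _marginal_scale_lp(self, params: Dict[str, float]) -> float:
        """Tag-marginalized log posterior of the scales (link fixed)."""
        try:
            # global_values raises if the map degenerates at any origin,
            # which is exactly the model's support boundary
            rho, p_loc, p_glob = self._mixture_values(params)
        except DegenerateGlobalMapError:
            return _NEG_INF
        return self._log_posterior(params, rho, p_loc, p_glob)

    def _marginal_scale_moves(self, params: Dict[str, float], lp: float,
                              rng: np.random.Generator) -> Tuple[Dict[str, float], float]:
        """Random-walk Metropolis on log(eps, xi) under the marginal target."""
        names = ("eps_x", "eps_y", "xi_x", "xi_y")
        for _ in range(self.config.marginal_moves):
            prop = dict(params)
            u = np.log([params[k] for k in names])
            u_new = u + self.config.marginal_step * rng.standard_normal(4)
            theta = np.exp(u_new)
            for k, v in zip(names, theta):
                prop[k] = float(v)
            if not (prop["xi_x"] > prop["eps_x"] and prop["xi_y"] > prop["eps_y"]):
                continue
            # symmetric proposal in u; the IG priors in _log_posterior are in
            # theta space, so add the log-space Jacobian sum(u) on each side
            lp_new = self._marginal_scale_lp(prop)
            if not np.isfinite(lp_new):
                continue
            log_ratio = (lp_new + u_new.sum()) - (lp + u.sum())
            if np.log(rng.random()) < log_ratio:
                params = prop
                lp = lp_new
        return params, lp

    # ---- initialization ----

    def _init_params(self, rng: np.random.Generator) -> Dict[str, float]:
        h = self.hyper
        d = self.data
        params: Dict[str, float] = {}
        if d.n > 0:
            m2x = float(np.median(d.dx**2)) + 1.0
            m2y = float(np.median(d.dy**2)) + 1.0
            eps_x = m2x * rng.uniform(0.05, 0.5)
            eps_y = m2y * rng.uniform(0.05, 0.5)
            xi_x = m2x * rng.uniform(2.0, 8.0)
            xi_y = m2y * rng.uniform(2.0, 8.0)
        else:
            eps_x = _prior_scale_draw(h, rng, "eps")
            eps_y = _prior_scale_draw(h, rng, "eps")
            xi_x, xi_y = np.inf, np.inf
            for _ in range(100):
                xi_x = _prior_scale_draw(h, rng, "xi")
                xi_y = _prior_scale_draw(h, rng, "xi")
                if xi_x > eps_x and xi_y > eps_y:
                    break
            xi_x = max(xi_x, 2.0 * eps_x)
            xi_y = max(xi_y, 2.0 * eps_y)
        if self.variant == "local_saliency":
            params["xi_x"], params["xi_y"] = xi_x, xi_y
            return params
        params.update(eps_x=eps_x, eps_y=eps_y, xi_x=max(xi_x, 1.5 * eps_x),
                      xi_y=max(xi_y, 1.5 * eps_y))
        if self.variant in ("full", "local_choice"):
            params["b"] = float(rng.normal(h.mu_b, h.sigma_b))
            params["s_o"] = float(rng.normal(h.mu_so, h.sigma_so))
        elif self.variant == "fixed_choice":
            params["rho_fixed"] = float(rng.beta(h.beta_a, h.beta_b))
        # a dispersed start must still be inside the model's support: shrink
        # the local scale / widen the global one until the clamped global
        # map keeps positive mass on every trial's grid
        if d.n > 0:
            for _ in range(30):
                try:
                    d.global_values(
                        params["eps_x"], params["eps_y"],
                        params["xi_x"], params["xi_y"],
                    )
                    break
                except DegenerateGlobalMapError:
                    params["eps_x"] *= 0.4
                    params["eps_y"] *= 0.4
                    params["xi_x"] *= 1.5
                    params["xi_y"] *= 1.5
            else:
                raise DegenerateGlobalMapError(
                    "could not find a non-degenerate starting point"
                )
        return params

    # ---- one chain ----

    def run_chain(self, rng: np.random.Generator,
                  init_params: Optional[Dict[str, float]] = None):
        cfg = self.config
        d = self.data
        if init_params is not None:
            params = self._init_params(rng)  # fill any missing entries
            params.update({k: float(v) for k, v in init_params.items()
                           if k in params})
        else:
            params = self._init_params(rng)
        empty = d.n == 0
        mixture = self.variant in MIXTURE_VARIANTS and not empty
        # start the mode indicators from an amplitude split (short saccades
        # local, long ones global) so every dispersed chain begins near the
        # data-supported basin rather than an all-one-mode configuration
        if mixture:
            amp2 = d.dx**2 + d.dy**2
            gamma = (amp2 < np.median(amp2)).astype(int)
            # a saccade landing inside the initial repulsion zone has zero
            # global density and must start in the local mode
            pg0 = d.global_values(
                params["eps_x"], params["eps_y"], params["xi_x"], params["xi_y"]
            )
            gamma[pg0 <= 0.0] = 1
        else:
            gamma = np.zeros(d.n, dtype=int)
        kept = {k: [] for k in self.scale_names + self.link_names}
        lp_trace: List[float] = []
        step = cfg.step_size
        averager = _DualAveraging(step, cfg.target_accept) if cfg.adapt_step_size else None
        n_accept = 0
        n_post = 0

        for it in range(cfg.n_iter):
            lp_iter = None
            # (1) link block given the current tags (grid-free, re-scanned)
            if mixture:
                if self.variant in ("full", "local_choice"):
                    for _ in range(max(1, cfg.link_sweeps)):
                        f = params["b"] * (d.design - params["s_o"])
                        w = sample_pg(f, rng)
                        x = d.design - params["s_o"]
                        params["b"] = sample_b(x, gamma, w, self.hyper, rng)
                        params["s_o"] = sample_s_o(
                            d.design, gamma, w, params["b"], self.hyper, rng
                        )
                else:
                    params["rho_fixed"] = sample_rho_fixed(gamma, self.hyper, rng)
            elif self.variant in ("full", "local_choice") and empty:
                params["b"] = float(rng.normal(self.hyper.mu_b, self.hyper.sigma_b))
                params["s_o"] = float(rng.normal(self.hyper.mu_so, self.hyper.sigma_so))
            elif self.variant == "fixed_choice" and empty:
                params["rho_fixed"] = float(
                    rng.beta(self.hyper.beta_a, self.hyper.beta_b)
                )

            # (2) HMC update of the covariance scales given the current tags
            logpost = self._scale_target(gamma if not empty else None)
            u = np.log([params[k] for k in self.scale_names])
            lp0, grad0 = logpost(u)
            u_new, accepted, aprob, lp_new, _ = hmc_transition(
                logpost, u, step, cfg.hmc_steps, rng, lp0, grad0
            )
            theta = np.exp(u_new)
            for k, v in zip(self.scale_names, theta):
                params[k] = float(v)
            if averager is not None and it < cfg.n_burn:
                step = averager.update(aprob)
                step = float(np.clip(step, 1e-5, 2.0))
                if it == cfg.n_burn - 1:
                    step = float(np.clip(averager.final_step, 1e-5, 2.0))

            # (2b) tag-marginalized Metropolis moves on the scales, which
            # escape metastable (scales, tags) configurations the
            # tag-conditional HMC update cannot leave
            if mixture and self.config.marginal_moves > 0:
                lp_marg = self._marginal_scale_lp(params)
                params, _ = self._marginal_scale_moves(params, lp_marg, rng)

            # (3) resample the tags under the updated parameters
            if mixture:
                rho, p_loc, p_glob = self._mixture_values(params)
                gamma = sample_gamma(rho, p_loc, p_glob, rng)
                lp_iter = self._log_posterior(params, rho, p_loc, p_glob)
            else:
                lp_iter = float(lp_new)

            if it >= cfg.n_burn:
                n_post += 1
                n_accept += int(accepted)
                if (it - cfg.n_burn) % cfg.thin == 0:
                    for k in self.scale_names + self.link_names:
                        kept[k].append(params[k])
                    lp_trace.append(lp_iter)
        accept_rate = n_accept / max(n_post, 1)
        return (
            {k: np.asarray(v) for k, v in kept.items()},
            np.asarray(lp_trace),
            accept_rate,
            gamma.copy(),
        )


def run_gibbs(
    table: Optional[pd.DataFrame],
    saliency_maps: Dict[object, SaliencyMap],
    variant: str = "full",
    hyper: Optional[Hyperparams] = None,
    config: Optional[GibbsConfig] = None,
    init_params: Optional[Sequence[Dict[str, float]]] = None,
) -> PosteriorSamples:
    """Fit one model (one subject's data) by Gibbs sampling.

    ``table`` may be ``None`` or empty, in which case the sampler draws
    from the prior.  Per-subject fitting is the caller's loop: pass the
    subset of the fixation table belonging to one subject.
    ``init_params`` (one dict per chain) restarts chains from saved
    states — e.g. the last draw of a previous run — to extend a fit;
    given the same states and seed the extension is reproducible.
    """
    config = config or GibbsConfig()
    data = SaccadeData(table, saliency_maps, variant=variant)
    if variant in MIXTURE_VARIANTS and data.n == 0 and table is not None and len(table) > 0:
        raise ValueError("inference requires at least one path with T >= 3")
    if hyper is None:
        if data.n > 0 and variant in ("full", "local_choice"):
            hyper = Hyperparams.default_for_data(float(data.design.mean()))
        else:
            hyper = Hyperparams()
    engine = _GibbsEngine(data, variant, hyper, config)
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    draws: Dict[str, List[np.ndarray]] = {}
    lps, rates = [], []
    final_gamma = None
    for c, cs in enumerate(chain_seeds):
        start = None
        if init_params is not None:
            start = dict(init_params[min(c, len(init_params) - 1)])
        kept, lp, rate, gamma = engine.run_chain(
            np.random.default_rng(cs), init_params=start
        )
        for k, v in kept.items():
            draws.setdefault(k, []).append(v)
        lps.append(lp)
        rates.append(rate)
        final_gamma = gamma
    post = PosteriorSamples(
        draws={k: np.stack(v) for k, v in draws.items()},
        log_post=np.stack(lps),
        accept_rate=np.asarray(rates),
        variant=variant,
        hyper=hyper,
        seed=config.seed,
        final_gamma=final_gamma,
    )
    if data.n > 0 and not post.converged(config.rhat_threshold):
        warnings.warn(
            f"inference may not have converged: R-hat = {post.rhat()}",
            RuntimeWarning,
        )
    return post
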