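"""JIT-compiled hot loops for the clamped global-map normalizers.

The Gibbs sampler evaluates, for every global-tagged saccade and every
leapfrog step, sums over all pixels of the clamped map
``max(s(z) n_xi(z) - n_eps(z), 0)`` together with the weighted sums that
make up its parameter gradient.  These loops dominate the fit cost; the
numba versions fuse the separable 1-D Gaussian tables into a single pass
over the grid for the whole saccade batch (each saccade indexing its own
image's raster).  Pure-numpy implementations with identical semantics
live in :mod:`gazemix.inference` and are used when numba is unavailable;
a regression test keeps the two in agreement.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is pre-installed in CI
    HAVE_NUMBA = False

    def njit(**kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=False, fastmath=False)
def global_sums(maps, img_idx, ex_xi, ey_xi, ex_ep, ey_ep, dx2, dy2,
                c_xi, c_ep, with_grad):
    """Per-saccade pixel sums of the clamped global map.

    Parameters
    ----------
    maps : (K, H, W) stacked saliency rasters
    img_idx : (m,) raster index per saccade
    ex_xi, ex_ep : (m, W) tables exp(-(x - x_prev)^2 / (2 var_x))
    ey_xi, ey_ep : (m, H) tables for the y axis
    dx2 : (m, W) squared x distances; dy2 : (m, H)
    c_xi, c_ep : density normalizing constants
    with_grad : bool, whether to accumulate the distance-weighted sums

    Returns
    -------
    (U, sa, sb, sa_dx2, sa_dy2, sb_dx2, sb_dy2) : (m,) arrays over the
    clamp-active region, where ``a = s n_xi`` and ``b = n_eps``.
    """
    m, w = ex_xi.shape
    h = ey_xi.shape[1]
    U = np.zeros(m)
    sa = np.zeros(m)
    sb = np.zeros(m)
    sa_dx2 = np.zeros(m)
    sa_dy2 = np.zeros(m)
    sb_dx2 = np.zeros(m)
    sb_dy2 = np.zeros(m)
    for i in range(m):
        s_map = maps[img_idx[i]]
        for y in range(h):
            ay = c_xi * ey_xi[i, y]
            by = c_ep * ey_ep[i, y]
            d2y = dy2[i, y]
            for x in range(w):
                a = s_map[y, x] * ay * ex_xi[i, x]
                b = by * ex_ep[i, x]
                u = a - b
                if u > 0.0:
                    U[i] += u
                    if with_grad:
                        sa[i] += a
                        sb[i] += b
                        sa_dx2[i] += a * dx2[i, x]
                        sa_dy2[i] += a * d2y
                        sb_dx2[i] += b * dx2[i, x]
                        sb_dy2[i] += b * d2y
    return U, sa, sb, sa_dx2, sa_dy2, sb_dx2, sb_dy2


@njit(cache=False, fastmath=False)
def localsal_sums(maps, img_idx, ex, ey, dx2, dy2, with_grad):
    """Per-saccade pixel sums of the saliency-modulated Gaussian (the
    local_saliency normalizer) and its distance-weighted gradient sums.

    Returns ``(U, s_dx2, s_dy2)``.
    """
    m, w = ex.shape
    h = ey.shape[1]
    U = np.zeros(m)
    s_dx2 = np.zeros(m)
    s_dy2 = np.zeros(m)
    for i in range(m):
        s_map = maps[img_idx[i]]
        for y in range(h):
            ey_i = ey[i, y]
            d2y = dy2[i, y]
            for x in range(w):
                a = s_map[y, x] * ey_i * ex[i, x]
                U[i] += a
                if with_grad:
                    s_dx2[i] += a * dx2[i, x]
                    s_dy2[i] += a * d2y
    return U, s_dx2, s_dy2
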