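"""Saliency maps: containers, I/O, empirical density estimation and
synthetic fixtures.

A saliency (priority) map is a non-negative raster over image pixels,
normalized to sum to one, interpreted as the probability that an average
viewer fixates each pixel.  Empirical maps are kernel-density estimates of
pooled fixation locations; synthetic maps are mixtures of random Gaussian
bumps over a uniform floor, used as stand-ins for empirical maps in tests
and simulations.

Coordinates are 0-based pixel indices, ``x`` indexing columns and ``y``
indexing rows; densities are evaluated at pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "SaliencyMap",
    "load_saliency_map",
    "save_saliency_map",
    "empirical_saliency",
    "synthetic_saliency",
]

_NORM_TOL = 1e-9


@dataclass
class SaliencyMap:
    """A normalized non-negative raster on an H x W pixel grid."""

    values: np.ndarray
    px_per_degree: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("saliency map must be a 2-D array")
        h, w = self.values.shape
        if h < 2 or w < 2:
            raise ValueError("saliency grid must be at least 2 x 2")
        if np.any(self.values < 0):
            raise ValueError("saliency values must be non-negative")
        total = self.values.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("saliency map must have positive finite mass")
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(
                "saliency map must sum to 1 (use SaliencyMap.from_unnormalized)"
            )
        if self.px_per_degree is not None and not self.px_per_degree > 0:
            raise ValueError("px_per_degree must be positive")

    @classmethod
    def from_unnormalized(
        cls, values: np.ndarray, px_per_degree: Optional[float] = None
    ) -> "SaliencyMap":
        values = np.asarray(values, dtype=float)
        total = values.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("cannot normalize a map with non-positive mass")
        return cls(values / total, px_per_degree=px_per_degree)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def n_pixels(self) -> int:
        return self.values.size

    def value_at(self, x, y):
        """Map value at integer pixel coordinates (x = column, y = row)."""
        xi = np.asarray(x, dtype=int)
        yi = np.asarray(y, dtype=int)
        return self.values[yi, xi]

    def uniform_like(self) -> "SaliencyMap":
        return SaliencyMap(
            np.full(self.shape, 1.0 / self.n_pixels),
            px_per_degree=self.px_per_degree,
        )


def load_saliency_map(path, px_per_degree: Optional[float] = None) -> SaliencyMap:
    """Read a dense row-major matrix text file (whitespace or comma
    delimited) and return it as a normalized saliency map."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    values = np.loadtxt(path, delimiter=delimiter)
    return SaliencyMap.from_unnormalized(values, px_per_degree=px_per_degree)


def save_saliency_map(smap: SaliencyMap, path) -> None:
    np.savetxt(path, smap.values)


def empirical_saliency(
    fixations,
    image_id,
    shape: Tuple[int, int],
    bandwidth: Optional[float] = None,
    px_per_degree: Optional[float] = None,
) -> SaliencyMap:
    """Gaussian kernel-density estimate of the fixation density of one image.

    All fixations recorded on ``image_id`` (pooled over subjects and trials)
    contribute one isotropic Gaussian kernel evaluated at pixel centers;
    the summed map is renormalized within the image (no wraparound or
    reflection at the boundary).

    Parameters
    ----------
    fixations : pandas.DataFrame
        Fixation table with at least ``image_id``, ``x`` and ``y`` columns.
    image_id :
        Image whose density is estimated.
    shape : (H, W)
        Grid geometry in pixels.
    bandwidth : float, optional
        Kernel standard deviation in pixels.  Defaults to one degree of
        visual angle when ``px_per_degree`` is given, else ``W / 35``.
    """
    h, w = shape
    sub = fixations[fixations["image_id"] == image_id]
    if len(sub) == 0:
        raise ValueError(f"no fixations recorded for image {image_id!r}")
    if bandwidth is None:
        bandwidth = px_per_degree if px_per_degree is not None else w / 35.0
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    fx = sub["x"].to_numpy(dtype=float)
    fy = sub["y"].to_numpy(dtype=float)
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    # separable kernels: sum_i exp(-(y-yi)^2/2h^2) exp(-(x-xi)^2/2h^2)
    ky = np.exp(-((ys[None, :] - fy[:, None]) ** 2) * inv2h2)  # (n, H)
    kx = np.exp(-((xs[None, :] - fx[:, None]) ** 2) * inv2h2)  # (n, W)
    values = np.einsum("nh,nw->hw", ky, kx)
    return SaliencyMap.from_unnormalized(values, px_per_degree=px_per_degree)


def synthetic_saliency(
    shape: Tuple[int, int],
    n_modes: int,
    seed,
    floor: float = 0.05,
    px_per_degree: Optional[float] = None,
) -> SaliencyMap:
    """Random multi-modal saliency fixture.

    A mixture of ``n_modes`` anisotropic Gaussian bumps with well-separated
    centers, over a uniform floor carrying ``floor`` of the total mass.
    Deterministic given ``seed`` (an int or a numpy Generator).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if not 0.0 <= floor < 1.0:
        raise ValueError("floor must be in [0, 1)")
    h, w = shape
    rng = np.random.default_rng(seed)
    extent = min(h, w)
    min_sep = 0.45 * extent / max(1.0, np.sqrt(n_modes))
    centers = []
    # rejection-sample mode centers so local maxima stay distinct
    for _ in range(10_000):
        if len(centers) == n_modes:
            break
        cand = np.array(
            [rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h)]
        )
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < n_modes:
        raise RuntimeError("could not place well-separated saliency modes")

    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    xg, yg = np.meshgrid(xs, ys)
    bumps = np.zeros((h, w))
    for cx, cy in centers:
        sx = rng.uniform(0.05, 0.12) * extent
        sy = rng.uniform(0.05, 0.12) * extent
        theta = rng.uniform(0.0, np.pi)
        weight = rng.uniform(0.5, 1.0)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xg - cx) * ct + (yg - cy) * st
        v = -(xg - cx) * st + (yg - cy) * ct
        bump = np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
        bumps += weight * bump / bump.sum()
    values = (1.0 - floor) * bumps / bumps.sum() + floor / (h * w)
    return SaliencyMap.from_unnormalized(values, px_per_degree=px_per_degree)
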