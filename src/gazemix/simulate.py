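"""Generative sampling of scan paths and synthetic cohorts.

Sampling from a probability map is exact categorical sampling over pixels
(inverse CDF on the flattened map); simulation and likelihood therefore
live on the same discrete measure.  The first two fixations of every path
are drawn independently from the saliency map; from the third fixation on,
a Bernoulli gate with per-step probability rho_t selects the local or the
global attention mode and the fixation is drawn from that mode's map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .fixations import COLUMNS, ScanPath, paths_to_table
from .maps import (
    global_map,
    local_map,
    local_saliency_map,
    rho_for_step,
)
from .params import DegenerateGlobalMapError, MIXTURE_VARIANTS, ModelParams
from .saliency import SaliencyMap, synthetic_saliency

__all__ = [
    "sample_from_map",
    "sample_scanpath",
    "sample_cohort",
    "synthetic_dataset",
    "SyntheticDataset",
    "DEFAULT_N_FIX",
]

#: default scan-path length: a 10 s viewing at 3-4 saccades per second
DEFAULT_N_FIX = 35


def sample_from_map(values: np.ndarray, rng: np.random.Generator) -> Tuple[int, int]:
    """Draw one pixel (x, y) from a normalized probability map."""
    flat = values.ravel()
    idx = np.searchsorted(np.cumsum(flat), rng.random() * flat.sum())
    idx = min(idx, flat.size - 1)
    y, x = np.unravel_index(idx, values.shape)
    return int(x), int(y)


def sample_scanpath(
    saliency: SaliencyMap,
    params: ModelParams,
    n_fix: int,
    rng,
    record_tags: bool = True,
) -> ScanPath:
    """Sample one scan path of ``n_fix`` fixations from a model variant.

    Latent local/global tags are recorded for mixture variants when
    ``record_tags`` is set; deterministic given the generator state.
    """
    if n_fix < 2:
        raise ValueError("a scan path needs at least 2 fixations")
    rng = np.random.default_rng(rng)
    mixture = params.variant in MIXTURE_VARIANTS
    xs = np.empty(n_fix)
    ys = np.empty(n_fix)
    tags = ["initial", "initial"] if (record_tags and mixture) else None
    for t in range(2):
        xs[t], ys[t] = sample_from_map(saliency.values, rng)
    for t in range(2, n_fix):
        z_prev = (xs[t - 1], ys[t - 1])
        z_prev2 = (xs[t - 2], ys[t - 2])
        if params.variant == "saliency_baseline":
            dist = saliency.values
        elif params.variant == "local_saliency":
            dist = local_saliency_map(z_prev, params, saliency)
        else:
            rho = rho_for_step(z_prev, z_prev2, params, saliency)
            take_local = rng.random() < rho
            if take_local:
                dist = local_map(z_prev, params, saliency.shape)
            else:
                try:
                    dist = global_map(z_prev, params, saliency)
                except DegenerateGlobalMapError as err:
                    raise DegenerateGlobalMapError(
                        f"degenerate global map at step {t + 1}: {err}"
                    ) from err
            if tags is not None:
                tags.append("local" if take_local else "global")
        xs[t], ys[t] = sample_from_map(dist, rng)
    return ScanPath(xs, ys, tags=tags)


def sample_cohort(
    saliency_maps: Dict[object, SaliencyMap],
    subject_params: Dict[object, ModelParams],
    n_fix: int,
    seed,
    record_tags: bool = True,
):
    """One scan path per (subject, image) pair, flattened to a fixation
    table; per-path tags returned alongside.

    Mirrors the experimental design of one trial per image per subject.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(len(subject_params) * len(saliency_maps))
    paths: Dict[tuple, ScanPath] = {}
    tags: Dict[tuple, list] = {}
    i = 0
    for subject_id, params in subject_params.items():
        for image_id, smap in saliency_maps.items():
            rng = np.random.default_rng(children[i])
            i += 1
            path = sample_scanpath(smap, params, n_fix, rng, record_tags=record_tags)
            key = (subject_id, image_id, 1)
            paths[key] = path
            if path.tags is not None:
                tags[key] = list(path.tags)
    return paths_to_table(paths), tags


@dataclass
class SyntheticDataset:
    """A simulated cohort with its generating ground truth."""

    table: pd.DataFrame
    saliency_maps: Dict[object, SaliencyMap]
    params: ModelParams
    tags: Dict[tuple, list]
    seed: int

    def ground_truth(self) -> dict:
        """Key-value record of the generating configuration (YAML/JSON-able)."""
        return {
            "seed": int(self.seed),
            "params": self.params.to_dict(),
            "tags": {"|".join(map(str, k)): v for k, v in self.tags.items()},
        }


def synthetic_dataset(
    params: ModelParams,
    n_subjects: int = 1,
    n_images: int = 30,
    n_fix: int = DEFAULT_N_FIX,
    shape: Tuple[int, int] = (128, 128),
    n_modes: int = 3,
    seed: int = 0,
    px_per_degree: Optional[float] = 4.0,
    map_floor: float = 0.2,
) -> SyntheticDataset:
    """Simulate a cohort from known parameters over synthetic saliency maps.

    Defaults emulate the size of one subject's experimental data: 30
    images with ~35 fixations each (10 s of viewing).  Every subject
    shares ``params``; per-image maps are independent synthetic fixtures.
    ``map_floor`` sets the uniform mass fraction of those maps; the
    default mimics the broad support of empirical fixation-density maps
    (kernel-density estimates are smooth and nowhere near zero over the
    image), which also keeps the global covariance well identified.
    """
    if n_fix < 3:
        raise ValueError("n_fix must be >= 3 for a modeled saccade to exist")
    ss = np.random.SeedSequence(seed)
    map_seeds, cohort_seed = ss.spawn(2)
    maps = {
        img: synthetic_saliency(
            shape, n_modes, s, floor=map_floor, px_per_degree=px_per_degree
        )
        for img, s in zip(range(n_images), map_seeds.spawn(n_images))
    }
    subject_params = {subj: params for subj in range(n_subjects)}
    table, tags = sample_cohort(maps, subject_params, n_fix, cohort_seed)
    return SyntheticDataset(table, maps, params, tags, seed)
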