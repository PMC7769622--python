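"""Likelihood-based predictive scores and saccade statistics.

The model's per-step conditional distribution over pixels (given the
*observed* history, i.e. teacher forcing) is treated as a probabilistic
classifier of the upcoming fixation and scored three ways:

- **AUC-Borji** — ROC area with the map values at true fixations as
  positives and map values at uniformly sampled pixels as negatives.
- **NSS** — mean of the per-step z-scored (population std) map at the
  true fixations.
- **Information Gain** — mean log2-likelihood advantage per fixation over
  a uniform-over-pixels baseline, in bit/fix.

Saccade-statistics analyses (amplitude density inputs, amplitude
autocorrelation, direction and direction-change distributions,
per-subject moments) and a by-image k-fold cross-validation harness
complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import r2_score
from statsmodels.tsa.stattools import acf as _sm_acf

from .fixations import ScanPath, table_to_paths
from .inference import GibbsConfig, run_gibbs
from .maps import step_distribution
from .params import Hyperparams, LOGLIK_FLOOR, ModelParams
from .saliency import SaliencyMap

__all__ = [
    "ScoreReport",
    "step_prediction_maps",
    "auc_from_scores",
    "auc_borji",
    "nss",
    "information_gain",
    "score_paths",
    "saccade_statistics",
    "amplitude_autocorrelation",
    "subject_moments",
    "coefficient_of_determination",
    "make_folds",
    "crossvalidate",
]


@dataclass
class ScoreReport:
    """AUC / NSS / IG of one model on one set of scan paths."""

    auc: float
    nss: float
    ig: float
    n_fix: int


def step_prediction_maps(
    path: ScanPath,
    params: ModelParams,
    saliency: SaliencyMap,
    include_initial: bool = True,
):
    """Yield ``(prob_map, (x, y))`` per scored fixation of one path.

    The first two fixations are modeled by the saliency map itself; later
    fixations by the variant's step distribution conditioned on the
    observed history.
    """
    xs = path.xs.astype(int)
    ys = path.ys.astype(int)
    if include_initial:
        for t in (0, 1):
            yield saliency.values, (xs[t], ys[t])
    for t in range(2, len(xs)):
        dist = step_distribution(
            (xs[t - 1], ys[t - 1]), (xs[t - 2], ys[t - 2]), params, saliency
        )
        yield dist, (xs[t], ys[t])


def auc_from_scores(positives: np.ndarray, negatives: np.ndarray) -> float:
    """ROC area via midranks (equivalent to trapezoidal integration of the
    ROC curve with tie handling)."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative score")
    if np.ptp(np.concatenate([pos, neg])) == 0.0:
        warnings.warn("all scores identical; AUC is chance level", RuntimeWarning)
        return 0.5
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _uniform_negatives(shape, n, rng) -> Tuple[np.ndarray, np.ndarray]:
    h, w = shape
    return rng.integers(0, w, size=n), rng.integers(0, h, size=n)


def auc_borji(
    prediction_maps: Iterable,
    n_negatives_per_positive: int = 10,
    rng=None,
) -> float:
    """AUC-Borji over an iterable of ``(map, (x, y))`` pairs."""
    rng = np.random.default_rng(rng)
    pos, neg = [], []
    for values, (x, y) in prediction_maps:
        pos.append(values[y, x])
        nx, ny = _uniform_negatives(values.shape, n_negatives_per_positive, rng)
        neg.extend(values[ny, nx])
    return auc_from_scores(np.asarray(pos), np.asarray(neg))


def nss(prediction_maps: Iterable) -> float:
    """Normalized scanpath saliency: mean z-value of each step's map at the
    true fixation (z-scored over pixels with population std; constant maps
    contribute 0)."""
    vals = []
    for values, (x, y) in prediction_maps:
        std = values.std()
        if std == 0.0:
            warnings.warn("constant prediction map contributes NSS 0", RuntimeWarning)
            vals.append(0.0)
        else:
            vals.append((values[y, x] - values.mean()) / std)
    if not vals:
        raise ValueError("no fixations to score")
    return float(np.mean(vals))


def information_gain(prediction_maps: Iterable) -> float:
    """Mean over fixations of log2 p_model(z_t) + log2(n_pixels), bit/fix."""
    gains = []
    for values, (x, y) in prediction_maps:
        p = max(float(values[y, x]), LOGLIK_FLOOR)
        gains.append(np.log2(p) + np.log2(values.size))
    if not gains:
        raise ValueError("no fixations to score")
    return float(np.mean(gains))


def score_paths(
    paths: Dict[tuple, ScanPath],
    params: ModelParams,
    saliency_maps: Dict[object, SaliencyMap],
    n_negatives_per_positive: int = 10,
    rng=None,
    include_initial: bool = True,
) -> ScoreReport:
    """AUC / NSS / IG of one parameter configuration on a set of paths.

    Paths are keyed by (subject_id, image_id, trial_id); each is scored
    against its image's saliency map.
    """
    rng = np.random.default_rng(rng)
    pos_scores: List[float] = []
    neg_scores: List[float] = []
    z_vals: List[float] = []
    gains: List[float] = []
    for (subject_id, image_id, trial_id), path in paths.items():
        smap = saliency_maps[image_id]
        for values, (x, y) in step_prediction_maps(
            path, params, smap, include_initial=include_initial
        ):
            v = values[y, x]
            pos_scores.append(v)
            nx, ny = _uniform_negatives(values.shape, n_negatives_per_positive, rng)
            neg_scores.extend(values[ny, nx])
            std = values.std()
            z_vals.append(0.0 if std == 0.0 else (v - values.mean()) / std)
            gains.append(np.log2(max(float(v), LOGLIK_FLOOR)) + np.log2(values.size))
    return ScoreReport(
        auc=auc_from_scores(np.asarray(pos_scores), np.asarray(neg_scores)),
        nss=float(np.mean(z_vals)),
        ig=float(np.mean(gains)),
        n_fix=len(pos_scores),
    )


# ---------------------------------------------------------------------------
# saccade statistics
# ---------------------------------------------------------------------------


def _as_paths(data) -> Dict[tuple, ScanPath]:
    if isinstance(data, pd.DataFrame):
        return table_to_paths(data)
    if isinstance(data, ScanPath):
        return {("_", "_", 1): data}
    return dict(data)


def wrap_degrees(angle) -> np.ndarray:
    """Wrap angles to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped


def saccade_statistics(data) -> pd.DataFrame:
    """Per-saccade amplitude, direction and direction change.

    Directions use the mathematical convention on image coordinates
    (``atan2(dy, dx)`` with y increasing downward), in degrees in
    (-180, 180]; direction change is the circular difference of
    consecutive saccade directions.  Returns one row per saccade with the
    direction change NaN for each path's first saccade.
    """
    rows = []
    for key, path in _as_paths(data).items():
        dx = np.diff(path.xs)
        dy = np.diff(path.ys)
        amp = np.hypot(dx, dy)
        direc = wrap_degrees(np.degrees(np.arctan2(dy, dx)))
        change = np.full(len(amp), np.nan)
        if len(amp) >= 2:
            change[1:] = wrap_degrees(np.diff(direc))
        for i in range(len(amp)):
            rows.append(
                {
                    "subject_id": key[0],
                    "image_id": key[1],
                    "trial_id": key[2],
                    "saccade_index": i + 1,
                    "amplitude": amp[i],
                    "direction": direc[i],
                    "direction_change": change[i],
                }
            )
    return pd.DataFrame(rows)


def amplitude_autocorrelation(data, max_lag: int = 20) -> np.ndarray:
    """Mean over paths of the sample autocorrelation of the saccade
    amplitude sequence, for lags 0..max_lag.  Paths too short for a lag
    are excluded at that lag."""
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    acfs = []
    for path in _as_paths(data).values():
        amp = path.amplitudes()
        if len(amp) < 3 or np.ptp(amp) == 0.0:
            continue
        nlags = min(max_lag, len(amp) - 2)
        r = _sm_acf(amp, nlags=nlags, fft=False)
        padded = np.full(max_lag + 1, np.nan)
        padded[: len(r)] = r
        acfs.append(padded)
    if not acfs:
        raise ValueError("no path long enough for the requested lags")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.asarray(acfs), axis=0)


def subject_moments(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of saccade amplitude per subject."""
    stats = saccade_statistics(table)
    out = (
        stats.groupby("subject_id")["amplitude"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "amplitude_mean", "std": "amplitude_std"})
    )
    return out


def coefficient_of_determination(observed, simulated) -> float:
    """R^2 = 1 - SS_res / SS_tot between per-subject observed and simulated
    values; <= 0 for a subject-independent predictor, reported as is."""
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if len(observed) < 2:
        raise ValueError("R^2 needs at least 2 subjects")
    return float(r2_score(observed, simulated))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def make_folds(image_ids: Sequence, k: int, rng) -> List[np.ndarray]:
    """Disjoint covering k-fold split of the images (seeded shuffle)."""
    ids = np.asarray(list(image_ids))
    if k < 2 or k > len(ids):
        raise ValueError("k must be between 2 and the number of images")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(len(ids))
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def crossvalidate(
    table: pd.DataFrame,
    saliency_maps: Dict[object, SaliencyMap],
    variant: str = "full",
    hyper: Optional[Hyperparams] = None,
    k: int = 5,
    config: Optional[GibbsConfig] = None,
    rng=None,
    n_negatives_per_positive: int = 10,
    posterior_draws_per_fold: int = 0,
) -> pd.DataFrame:
    """By-image k-fold cross-validation with per-subject models.

    For each fold and subject, the model is fitted on the training-fold
    images and scored (AUC/NSS/IG at the posterior-mean parameters) on the
    held-out test images.  When ``posterior_draws_per_fold`` > 0, that
    many posterior draws are also scored to quantify parameter
    uncertainty (rows flagged by the ``draw`` column; -1 is the
    posterior-mean row).

    Returns a tidy DataFrame: subject, fold, draw, auc, nss, ig, n_fix.
    """
    rng = np.random.default_rng(rng)
    config = config or GibbsConfig()
    image_ids = list(saliency_maps.keys())
    folds = make_folds(image_ids, k, rng)
    for f in folds:
        if len(f) == 0:
            raise ValueError("a fold has no test images")
    rows = []
    for fold_i, test_ids in enumerate(folds):
        test_set = set(test_ids.tolist())
        train_tab = table[~table["image_id"].isin(test_set)]
        test_tab = table[table["image_id"].isin(test_set)]
        for subject in sorted(table["subject_id"].unique()):
            sub_train = train_tab[train_tab["subject_id"] == subject]
            sub_test = test_tab[test_tab["subject_id"] == subject]
            if len(sub_train) == 0 or len(sub_test) == 0:
                raise ValueError(
                    f"subject {subject!r} has no data in fold {fold_i}"
                )
            train_maps = {
                i: saliency_maps[i] for i in saliency_maps if i not in test_set
            }
            fold_cfg = GibbsConfig(
                **{**config.__dict__, "seed": int(rng.integers(2**31 - 1))}
            )
            post = run_gibbs(sub_train, train_maps, variant, hyper, fold_cfg)
            test_paths = table_to_paths(sub_test)

            def _score(params, draw):
                rep = score_paths(
                    test_paths,
                    params,
                    saliency_maps,
                    n_negatives_per_positive=n_negatives_per_positive,
                    rng=rng,
                )
                rows.append(
                    {
                        "subject": subject,
                        "fold": fold_i,
                        "draw": draw,
                        "auc": rep.auc,
                        "nss": rep.nss,
                        "ig": rep.ig,
                        "n_fix": rep.n_fix,
                    }
                )

            _score(post.mean_params(), -1)
            if posterior_draws_per_fold > 0:
                names = post.param_names
                flat = {k2: post.draws[k2].reshape(-1) for k2 in names}
                n_avail = len(next(iter(flat.values())))
                picks = rng.choice(
                    n_avail, size=min(posterior_draws_per_fold, n_avail), replace=False
                )
                for j, p in enumerate(picks):
                    kw = {k2: float(flat[k2][p]) for k2 in names}
                    kw["variant"] = variant
                    try:
                        _score(ModelParams(**kw), j)
                    except ValueError:
                        continue  # draw outside the xi > eps support
    return pd.DataFrame(rows)
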