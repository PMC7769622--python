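"""Fixation tables and scan paths.

A fixation table is a pandas DataFrame with the six columns
``subject_id, image_id, trial_id, fixation_index, x, y``; one row per
fixation, ``fixation_index`` strictly increasing from 1 within each trial.
A scan path is the ordered fixation sequence of a single trial, optionally
carrying the latent local/global tag of each fixation when the path was
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "ScanPath",
    "load_fixation_table",
    "save_fixation_table",
    "validate_fixation_table",
    "table_to_paths",
    "paths_to_table",
]

COLUMNS = ["subject_id", "image_id", "trial_id", "fixation_index", "x", "y"]

#: allowed per-fixation tags: the first two fixations are drawn directly
#: from the saliency map ("initial"); later ones from one attention mode
TAGS = ("initial", "local", "global")


@dataclass
class ScanPath:
    """Ordered fixation locations of one trial (pixel coordinates)."""

    xs: np.ndarray
    ys: np.ndarray
    tags: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if self.xs.shape != self.ys.shape or self.xs.ndim != 1:
            raise ValueError("xs and ys must be 1-D arrays of equal length")
        if len(self.xs) < 2:
            raise ValueError("a scan path needs at least 2 fixations")
        if self.tags is not None:
            if len(self.tags) != len(self.xs):
                raise ValueError("tags must have one entry per fixation")
            if list(self.tags[:2]) != ["initial", "initial"]:
                raise ValueError("the first two fixations must be tagged 'initial'")
            bad = set(self.tags) - set(TAGS)
            if bad:
                raise ValueError(f"unknown tags {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.xs)

    def check_in_grid(self, shape: Tuple[int, int]) -> None:
        h, w = shape
        if (
            np.any(self.xs < 0)
            or np.any(self.xs >= w)
            or np.any(self.ys < 0)
            or np.any(self.ys >= h)
        ):
            raise ValueError("scan path leaves the pixel grid")

    def amplitudes(self) -> np.ndarray:
        """Euclidean saccade lengths between consecutive fixations (px)."""
        return np.hypot(np.diff(self.xs), np.diff(self.ys))


def validate_fixation_table(
    table: pd.DataFrame, shape: Optional[Tuple[int, int]] = None
) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fixation table is missing columns {missing}")
    table = table[COLUMNS].copy()
    if shape is not None:
        h, w = shape
        bad = (
            (table["x"] < 0) | (table["x"] >= w) | (table["y"] < 0) | (table["y"] >= h)
        )
        if bad.any():
            rows = table.index[bad].tolist()
            raise ValueError(
                f"{bad.sum()} fixation(s) outside the {h}x{w} grid at rows {rows[:20]}"
            )
    for key, sub in table.groupby(["subject_id", "image_id", "trial_id"], sort=False):
        idx = sub["fixation_index"].to_numpy()
        if idx[0] != 1 or np.any(np.diff(idx) <= 0):
            raise ValueError(
                f"fixation_index must increase strictly from 1 within trial {key}"
            )
    return table


def load_fixation_table(path, shape: Optional[Tuple[int, int]] = None) -> pd.DataFrame:
    """Read a CSV/TSV fixation table (header-driven column order)."""
    table = pd.read_csv(path, sep=None, engine="python")
    return validate_fixation_table(table, shape=shape)


def save_fixation_table(table: pd.DataFrame, path) -> None:
    validate_fixation_table(table).to_csv(path, index=False)


def table_to_paths(table: pd.DataFrame) -> Dict[tuple, ScanPath]:
    """Split a fixation table into per-trial scan paths keyed by
    (subject_id, image_id, trial_id)."""
    paths: Dict[tuple, ScanPath] = {}
    for key, sub in table.groupby(["subject_id", "image_id", "trial_id"], sort=False):
        sub = sub.sort_values("fixation_index")
        paths[key] = ScanPath(
            sub["x"].to_numpy(dtype=float), sub["y"].to_numpy(dtype=float)
        )
    return paths


def paths_to_table(paths: Dict[tuple, ScanPath]) -> pd.DataFrame:
    rows = []
    for (subject_id, image_id, trial_id), path in paths.items():
        for i, (x, y) in enumerate(zip(path.xs, path.ys), start=1):
            rows.append((subject_id, image_id, trial_id, i, x, y))
    return pd.DataFrame(rows, columns=COLUMNS)
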