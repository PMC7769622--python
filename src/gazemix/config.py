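"""Run configuration and reproducibility plumbing for the CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .inference import GibbsConfig
from .params import Hyperparams, ModelParams, VARIANTS

__all__ = ["RunConfig", "load_config", "spawn_seeds", "write_manifest"]


@dataclass
class RunConfig:
    """Everything a workflow run needs, loadable from one YAML file."""

    variant: str = "full"
    grid_height: int = 128
    grid_width: int = 128
    px_per_degree: Optional[float] = 4.0
    n_subjects: int = 1
    n_images: int = 30
    n_fix: int = 35
    n_modes: int = 3
    seed: int = 0
    outdir: str = "gazemix_out"
    params: dict = field(default_factory=dict)
    hyper: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    _KNOWN = None  # populated below

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.grid_height, self.grid_width)

    def model_params(self) -> ModelParams:
        d = dict(self.params)
        d.setdefault("variant", self.variant)
        return ModelParams.from_dict(d)

    def hyperparams(self) -> Optional[Hyperparams]:
        return Hyperparams.from_dict(self.hyper) if self.hyper else None

    def gibbs_config(self, seed: Optional[int] = None) -> GibbsConfig:
        d = dict(self.sampler)
        d.setdefault("seed", self.seed if seed is None else seed)
        return GibbsConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__) - {"_KNOWN"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def spawn_seeds(master_seed: int, n: int) -> list:
    """Deterministic independent substream seeds from one master seed."""
    return [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(master_seed).spawn(n)
    ]


def write_manifest(outdir, config: RunConfig, extra: Optional[dict] = None) -> Path:
    """Write a manifest sufficient to reproduce the run bit-for-bit."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
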