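"""Run configuration: every default reproduces the protocol constants
(partition coefficient 0.9; labeling efficiencies 0.85/0.98; bolus
durations 1.8/0.7 s; post-labeling delay 1.5 s; 10 inflow times 0.35-2.6 s;
background ROI width 5; erosion width 2; watershed percentile 0.70; FLAIR
factor 1.02; 1000 bootstrap samples)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import CohortSpec, PhantomSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "aslhemo_out"
    group: str = "sca"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    iwsa_percentile: float = 0.70
    erosion_width: int = 2
    flair_factor: float = 1.02
    background_roi_width: int = 5
    n_boot: int = 1000
    kinetic_model: str = "simplified"

    def __post_init__(self) -> None:
        # one seed steers every stochastic stage
        self.phantom = dataclasses.replace(self.phantom, seed=self.seed,
                                           group=self.group)
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["shape"] = list(self.phantom.shape)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    phantom_kwargs = raw.pop("phantom", {}) or {}
    if "shape" in phantom_kwargs:
        phantom_kwargs["shape"] = tuple(phantom_kwargs["shape"])
    cohort_kwargs = raw.pop("cohort", {}) or {}
    cfg = RunConfig(**raw)
    if phantom_kwargs:
        cfg.phantom = dataclasses.replace(cfg.phantom, **phantom_kwargs)
    if cohort_kwargs:
        cfg.cohort = dataclasses.replace(cfg.cohort, **cohort_kwargs)
    cfg.__post_init__()
    return cfg
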