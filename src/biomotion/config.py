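"""Structured plain-text configuration (YAML) with documented defaults.

Sections mirror the processing stages: gabor, abm, flow, fuzzy, snn,
pipeline.  ``load_config`` accepts a partial file and fills the rest
with defaults; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["GaborConfig", "AbmConfig", "FlowConfig", "FuzzyConfig",
           "SnnConfig", "PipelineConfig", "Config", "load_config",
           "save_config", "default_config"]


@dataclass
class GaborConfig:
    n_orientations: int = 8
    n_scales: int = 2
    base_size: int = 17
    omega0: float | None = None     # default: wavelength (base_size+1)/2
    scale_step: float = float(np.sqrt(2.0))
    gamma: float = 0.5
    sigma_factor: float = 0.5


@dataclass
class AbmConfig:
    n_elements: int = 12
    saturation: float = 6.0
    inhibition_radius: int | None = None  # default: half kernel size
    location_bound: int = 2
    orientation_bound: int = 1
    roi_margin: int = 4                   # ROI dilation for t-1 tracking


@dataclass
class FlowConfig:
    rho: float = 0.5
    xi: float = 0.02
    n_levels: int = 4
    n_outer: int = 6
    n_inner: int = 3
    n_sweeps: int = 20
    charbonnier_eps: float = 1e-3
    presmooth_sigma: float = 0.8
    sad_block: int = 8
    sad_search_radius: int = 4


@dataclass
class FuzzyConfig:
    tau: float = 0.1
    beta: float = 2.0
    beta_prime: float | None = None   # defaults to beta
    n_max: int = 3
    margin: float = 0.05
    enable_left_right: bool = False


@dataclass
class SnnConfig:
    p1: float = 0.0
    p2: float = 0.1
    match_mode: str = "retained"      # 'retained' (P_1..P_S + F_t) | 'final'


@dataclass
class PipelineConfig:
    frame_height: int = 142
    frame_width: int = 200
    n_snippets: int = 5
    select_count: int = 5
    select_stride: int = 2
    mirror_augment: bool = False
    speed_quantile: float = 0.9       # ROI = flow speed above this quantile
    use_abm_score: bool = False       # ABM is localization-only by default
    gate_enabled: bool = True


@dataclass
class Config:
    gabor: GaborConfig = field(default_factory=GaborConfig)
    abm: AbmConfig = field(default_factory=AbmConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    snn: SnnConfig = field(default_factory=SnnConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {f.name: f for f in fields(Config)}


def default_config() -> Config:
    return Config()


def _apply(section_obj, data: dict, section: str):
    known = {f.name for f in fields(section_obj)}
    for key, val in data.items():
        if key not in known:
            raise ValueError(f"unknown key [{section}] {key!r}")
        setattr(section_obj, key, val)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> Config:
    cfg = Config()
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for sec, vals in overrides.items():
            data.setdefault(sec, {}).update(vals)
    for sec, vals in data.items():
        if sec not in _SECTIONS:
            raise ValueError(f"unknown config section {sec!r}")
        if vals:
            _apply(getattr(cfg, sec), vals, sec)
    return cfg


def save_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
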