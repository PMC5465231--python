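"""Pipeline configuration: one object holding every threshold and
registration parameter, loadable from a YAML key-value file.

FF thresholds are written in percent in configuration files (the way they
are quoted clinically: fine adjustment >= 40 %, skin constraint <= 30 %)
and converted to fractions at parse time; internally everything is a
fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .fusion import VotingParams
from .preprocess import BackgroundParams, SkinStripParams
from .registration import AffineStageParams, ElasticStageParams, RegistrationParams
from .segment import FineAdjustParams, RefineParams

__all__ = ["PipelineConfig", "load_config", "default_config", "config_to_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    background: BackgroundParams = field(default_factory=BackgroundParams)
    skin: SkinStripParams = field(default_factory=SkinStripParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    voting: VotingParams = field(default_factory=VotingParams)
    fine: FineAdjustParams = field(default_factory=FineAdjustParams)
    refine: RefineParams = field(default_factory=RefineParams)
    backend: str = "sitk"
    slices: str = "even"


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _pct(value: Any) -> float:
    return float(value) / 100.0


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing keys fall back to the defaults.

    Recognised sections and keys (FF thresholds in percent)::

        background: {sum_signal_threshold: auto | <float>, auto_fraction: 0.05}
        skin: {ff_max_pct: 30, r2s_min: 80, closing_se: 5,
               final_erosion_se: 7, max_iterations: 50}
        registration:
          seed: 20170608
          affine: {resolutions: 4, max_iterations: 3000, sampling_fraction: 0.25}
          elastic: {resolutions: 4, max_iterations: 7000,
                    final_grid_spacing_mm: 20, sampling_fraction: 0.25}
        voting: {binarize_at: 0.5}
        fine: {ff_min_pct: 40, r2s_max: 50}
        refine: {dilation_se: 3, erosion_se: 3}
        backend: sitk | synthetic
        slices: even | odd | all
    """
    if path is None:
        return default_config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = default_config()

    if "background" in raw:
        cfg = replace(cfg, background=BackgroundParams(**raw["background"]))
    if "skin" in raw:
        s = dict(raw["skin"])
        if "ff_max_pct" in s:
            s["ff_max"] = _pct(s.pop("ff_max_pct"))
        cfg = replace(cfg, skin=SkinStripParams(**s))
    if "registration" in raw:
        r = dict(raw["registration"])
        affine = AffineStageParams(**r.pop("affine", {}))
        elastic = ElasticStageParams(**r.pop("elastic", {}))
        cfg = replace(
            cfg, registration=RegistrationParams(affine=affine, elastic=elastic, **r)
        )
    if "voting" in raw:
        cfg = replace(cfg, voting=VotingParams(**raw["voting"]))
    if "fine" in raw:
        f = dict(raw["fine"])
        if "ff_min_pct" in f:
            f["ff_min"] = _pct(f.pop("ff_min_pct"))
        cfg = replace(cfg, fine=FineAdjustParams(**f))
    if "refine" in raw:
        r = dict(raw["refine"])
        if "background" in r:
            r["background"] = BackgroundParams(**r["background"])
        cfg = replace(cfg, refine=RefineParams(**r))
    if "backend" in raw:
        cfg = replace(cfg, backend=str(raw["backend"]))
    if "slices" in raw:
        cfg = replace(cfg, slices=str(raw["slices"]))
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Flatten a config to plain types (for JSON provenance reports)."""
    return {
        "background": asdict(cfg.background),
        "skin": asdict(cfg.skin),
        "registration": asdict(cfg.registration),
        "voting": asdict(cfg.voting),
        "fine": asdict(cfg.fine),
        "refine": asdict(cfg.refine),
        "backend": cfg.backend,
        "slices": cfg.slices,
    }
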