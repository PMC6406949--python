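"""Run configuration: one YAML file wiring every pipeline stage.

Layout (all blocks optional; defaults shown in the dataclasses)::

    input: video.tif            # for detect / run-all on existing footage
    pixel_scale: 1.0            # um per px
    frame_interval: 0.01        # s per frame
    seed: 0
    log_level: INFO
    scene: { ... SceneConfig fields ... }
    background: { K: 5, alpha: 0.01, ... }
    tracking: { gate_radius: 12, min_blob_area: 30, ... }
    analysis:
      rois:
        separation: [100, 118, 120, 160]   # row0, col0, row1, col1
        waste: [8, 146, 64, 160]
        weir: { origin: [0, 20], angle: 45.0, halfwidth: 8.0 }
      elongation_threshold: 1.4
      ...
    stats:
      baselines_per_ml: { erythrocyte: 5.0e9, leukocyte: 5.0e6 }
      volume_ml: 2.0
      efficiency_mode: per_trial_mean
      depletion_rounding: none

Every numeric field is validated against its stage's invariants before any
frame is read; validation errors name the failing field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .analysis import AnalysisThresholds
from .background import MixtureParams
from .geometry import Rect, RoiSet, WeirBand
from .scene import SceneConfig, ConfigurationError
from .tracking import TrackingParams


@dataclass
class StatsConfig:
    baselines_per_ml: Dict[str, float] = field(
        default_factory=lambda: {"erythrocyte": 5e9, "leukocyte": 5e6}
    )
    volume_ml: float = 2.0
    efficiency_mode: str = "per_trial_mean"
    depletion_rounding: str = "none"

    def validate(self) -> None:
        if self.volume_ml <= 0:
            raise ConfigurationError("stats.volume_ml must be positive")
        if self.efficiency_mode not in ("per_trial_mean", "pooled"):
            raise ConfigurationError("stats.efficiency_mode must be per_trial_mean or pooled")
        if self.depletion_rounding not in ("integer", "one_decimal", "none"):
            raise ConfigurationError(
                "stats.depletion_rounding must be integer, one_decimal or none"
            )
        for cls, v in self.baselines_per_ml.items():
            if v <= 0:
                raise ConfigurationError(f"stats.baselines_per_ml.{cls} must be positive")


@dataclass
class RunConfig:
    input: Optional[str] = None
    pixel_scale: float = 1.0
    frame_interval: float = 0.01
    seed: int = 0
    log_level: str = "INFO"
    scene: SceneConfig = field(default_factory=SceneConfig)
    background: MixtureParams = field(default_factory=MixtureParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    analysis: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    rois: Optional[RoiSet] = None  # default: derived from the scene block
    stats: StatsConfig = field(default_factory=StatsConfig)

    def roi_set(self) -> RoiSet:
        return self.rois if self.rois is not None else self.scene.roi_set()

    def validate(self, require_input: bool = False) -> None:
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be positive")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        if require_input:
            if self.input is None:
                raise ConfigurationError("input path is required for this command")
            if not Path(self.input).exists():
                raise ConfigurationError(f"input path {self.input} does not exist")
        _named("scene", self.scene.validate)
        _named("background", self.background.validate)
        _named("tracking", self.tracking.validate)
        _named("analysis", self.analysis.validate)
        _named("stats", self.stats.validate)
        self.roi_set()  # raises if ROIs overlap


def _named(block: str, validate) -> None:
    try:
        validate()
    except (ValueError, ConfigurationError) as exc:
        raise ConfigurationError(f"{block}: {exc}") from exc


def _parse_rois(d: dict) -> RoiSet:
    weir = d["weir"]
    origin = tuple(float(v) for v in weir["origin"])
    angle = math.radians(float(weir.get("angle", 45.0)))
    length = float(weir.get("length", 500.0))
    p1 = (origin[0] + length * math.sin(angle), origin[1] + length * math.cos(angle))
    if "end" in weir:
        p1 = tuple(float(v) for v in weir["end"])
    return RoiSet(
        separation=Rect.from_sequence(d["separation"]),
        waste=Rect.from_sequence(d["waste"]),
        weir=WeirBand(origin, p1, float(weir.get("halfwidth", 8.0))),
    )


_REQUIRED_TOP = ("pixel_scale",)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    cfg = RunConfig()
    for key in _REQUIRED_TOP:
        if key not in d:
            raise ConfigurationError(f"missing required field {key!r}")
    for key in ("input", "pixel_scale", "frame_interval", "seed", "log_level"):
        if key in d:
            setattr(cfg, key, d[key])
    if "scene" in d:
        scene_dict = dict(d["scene"])
        scene_dict.setdefault("pixel_scale", cfg.pixel_scale)
        scene_dict.setdefault("frame_interval", cfg.frame_interval)
        scene_dict.setdefault("seed", cfg.seed)
        try:
            cfg.scene = SceneConfig.from_dict(scene_dict)
        except TypeError as exc:
            raise ConfigurationError(f"scene: {exc}") from exc
    else:
        cfg.scene.pixel_scale = cfg.pixel_scale
        cfg.scene.seed = cfg.seed
    for key, cls in (("background", MixtureParams), ("tracking", TrackingParams),
                     ("stats", StatsConfig)):
        if key in d:
            try:
                setattr(cfg, key, cls(**d[key]))
            except TypeError as exc:
                raise ConfigurationError(f"{key}: {exc}") from exc
    if "analysis" in d:
        a = dict(d["analysis"])
        roi_dict = a.pop("rois", None)
        try:
            cfg.analysis = AnalysisThresholds(**a)
        except TypeError as exc:
            raise ConfigurationError(f"analysis: {exc}") from exc
        if roi_dict is not None:
            try:
                cfg.rois = _parse_rois(roi_dict)
            except (KeyError, ValueError) as exc:
                raise ConfigurationError(f"analysis.rois: {exc}") from exc
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    from dataclasses import asdict

    d = {
        "input": cfg.input,
        "pixel_scale": cfg.pixel_scale,
        "frame_interval": cfg.frame_interval,
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "scene": cfg.scene.to_dict(),
        "background": asdict(cfg.background),
        "tracking": asdict(cfg.tracking),
        "analysis": asdict(cfg.analysis),
        "stats": asdict(cfg.stats),
    }
    if cfg.rois is not None:
        d["analysis"]["rois"] = {
            "separation": list(asdict(cfg.rois.separation).values()),
            "waste": list(asdict(cfg.rois.waste).values()),
            "weir": {
                "origin": list(cfg.rois.weir.p0),
                "end": list(cfg.rois.weir.p1),
                "halfwidth": cfg.rois.weir.halfwidth,
            },
        }
    return d
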