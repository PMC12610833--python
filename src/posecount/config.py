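"""Resolved configuration for the assessment pipeline.

All empirical constants live here with their defaults: the 150 degree
pull-up elbow extension threshold; the 140/15/140 degree push-up thresholds;
the variance stability bound of 30; the inter-frame correction threshold of
1/30th of the frame dimension and the 10-frame smoothing window. A YAML file
may override any subset; unknown keys are rejected so typos cannot silently
fall back to defaults. The fully resolved configuration is echoed into every
assessment result.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .errors import ParameterError


@dataclass
class IOSection:
    side_policy: str = "mean"       # left | right | mean
    index_base: int = 0             # first frame number used by the producer


@dataclass
class PreprocessSection:
    enabled: bool = True            # master switch for the correction+smoothing pass
    correct: bool = True
    smooth: bool = True
    t_fraction: float = 1.0 / 30.0  # correction threshold, fraction of frame dim
    window: int = 10                # smoothing window, frames
    reference: str = "corrected"    # corrected | raw


@dataclass
class CalibrationSection:
    window: int = 30                # plateau window, frames (~1 s at 30 FPS)
    var_threshold: float = 30.0     # variance stability bound
    eye_threshold_mode: str = "calibrated"  # calibrated | per_frame


@dataclass
class PullupSection:
    elbow_angle: float = 150.0


@dataclass
class PushupSection:
    elbow_extension: float = 140.0
    torso_angle: float = 15.0
    body_extension: float = 140.0


@dataclass
class SitupSection:
    sit_up: Optional[float] = None  # None -> 0.5 x median session torso length
    sit_down: float = 15.0


@dataclass
class ThresholdsSection:
    pullup: PullupSection = field(default_factory=PullupSection)
    pushup: PushupSection = field(default_factory=PushupSection)
    situp: SitupSection = field(default_factory=SitupSection)


@dataclass
class FsmSection:
    pullup_s1_down: str = "s4"      # s4 (prose reading) | s2 (printed table)


@dataclass
class Config:
    io: IOSection = field(default_factory=IOSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    calibration: CalibrationSection = field(default_factory=CalibrationSection)
    thresholds: ThresholdsSection = field(default_factory=ThresholdsSection)
    fsm: FsmSection = field(default_factory=FsmSection)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def _apply(obj: Any, data: Dict[str, Any], path: str = "") -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in fields:
            raise ParameterError(f"unknown config key {path + key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ParameterError(f"config key {path + key!r} must be a mapping")
            _apply(current, value, path + key + ".")
        else:
            setattr(obj, key, value)


def config_from_dict(data: Optional[Dict[str, Any]]) -> Config:
    """Build a :class:`Config` from a (possibly partial) nested mapping."""
    cfg = Config()
    if data:
        _apply(cfg, data)
    return cfg


def load_config(path: Optional[str | Path] = None) -> Config:
    """Load configuration from a YAML file; defaults when ``path`` is None."""
    if path is None:
        return Config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: config root must be a mapping")
    return config_from_dict(data)
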