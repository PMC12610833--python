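"""End-to-end session assessment.

``assess`` runs the full two-pass pipeline on one keypoint sequence:

1. convert to pixel coordinates;
2. inter-frame flying-point correction and sliding-window smoothing;
3. calibration pre-pass over the whole sequence (bar height and eye-height
   threshold for pull-ups, minimum shoulder height for push-ups, torso-scaled
   distance threshold for sit-ups);
4. per-frame posture judgment;
5. finite-state machine fold producing the repetition count and trace.

Calibration deliberately consumes the entire session before any frame is
labeled (offline, video-mode processing); there is no streaming mode. The
result is deterministic given the sequence and configuration and carries
every intermediate needed to reproduce the count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np

from . import calibration as _calib
from .config import Config
from .errors import EmptyInputError, ParameterError, PoseCountError
from .fsm import AssessmentTrace, build_fsm, fsm_run
from .geometry import point_distance
from .judgment import (
    FrameFeatures,
    PostureLabel,
    PullUpThresholds,
    PushUpThresholds,
    SitUpThresholds,
    extract_features,
    pullup_F,
    pushup_F,
    situp_F,
)
from .model import KeypointSequence, Role, landmark_series, read_keypoint_sequence, to_pixel
from .preprocess import PreprocessParams, preprocess

EXERCISES = ("pullup", "pushup", "situp")


@dataclass
class AssessmentResult:
    """Everything one session assessment produced."""

    exercise: str
    count: int
    calibration: _calib.CalibrationResult
    labels: List[PostureLabel]
    trace: AssessmentTrace
    features: List[FrameFeatures]
    config_echo: Dict[str, Any]
    warnings: List[str] = field(default_factory=list)

    def to_dict(self, include_frames: bool = True) -> Dict[str, Any]:
        doc: Dict[str, Any] = {
            "exercise": self.exercise,
            "count": self.count,
            "calibration": self.calibration.to_dict(),
            "warnings": list(self.warnings),
            "config": self.config_echo,
            "n_frames": len(self.labels),
        }
        if include_frames:
            doc["labels"] = [l.value for l in self.labels]
            doc["states"] = [s.value for s in self.trace.states]
            doc["emissions"] = list(self.trace.emissions)
        return doc

    def save_json(self, path: str | Path, include_frames: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_frames=include_frames), fh, indent=2)


def _resolve_situp_threshold(
    seq: KeypointSequence, cfg: Config
) -> float:
    """Half the session median torso (shoulder-hip) length, in pixels."""
    shoulders = landmark_series(seq, Role.SHOULDER, cfg.io.side_policy)
    hips = landmark_series(seq, Role.HIP, cfg.io.side_policy)
    torso = [point_distance(s, h) for s, h in zip(shoulders, hips)]
    return 0.5 * float(np.median(torso))


def assess(
    seq: KeypointSequence, exercise: str, config: Optional[Config] = None
) -> AssessmentResult:
    """Assess one session and return the repetition count with its trace."""
    if exercise not in EXERCISES:
        raise ParameterError(f"unknown exercise {exercise!r}; expected one of {EXERCISES}")
    if len(seq) == 0:
        raise EmptyInputError("assess: empty sequence")
    cfg = config or Config()
    warnings: List[str] = []

    seq = to_pixel(seq.validate())
    if cfg.preprocess.enabled and (cfg.preprocess.correct or cfg.preprocess.smooth):
        params = PreprocessParams(
            t_fraction=cfg.preprocess.t_fraction,
            window=cfg.preprocess.window,
            reference=cfg.preprocess.reference,
        )
        seq = preprocess(
            seq, params, correct=cfg.preprocess.correct, smooth=cfg.preprocess.smooth
        )
    else:
        warnings.append("preprocessing disabled: flying points and jitter are not corrected")

    side = cfg.io.side_policy
    plateau = _calib.PlateauParams(
        window=cfg.calibration.window, var_threshold=cfg.calibration.var_threshold
    )
    features = extract_features(seq, exercise, side_policy=side)

    if exercise == "pullup":
        calib = _calib.calibrate_pullup(seq, plateau, side_policy=side)
        th_pu = PullUpThresholds(elbow_angle_threshold=cfg.thresholds.pullup.elbow_angle)
        per_frame = cfg.calibration.eye_threshold_mode == "per_frame"
        labels = [pullup_F(f, calib, th_pu, per_frame_elbow=per_frame) for f in features]
    elif exercise == "pushup":
        calib = _calib.calibrate_pushup(seq, side_policy=side)
        th_ps = PushUpThresholds(
            elbow_extension_threshold=cfg.thresholds.pushup.elbow_extension,
            torso_angle_threshold=cfg.thresholds.pushup.torso_angle,
            body_extension_threshold=cfg.thresholds.pushup.body_extension,
        )
        labels = [pushup_F(f, calib, th_ps) for f in features]
    else:
        sit_up = cfg.thresholds.situp.sit_up
        if sit_up is None:
            sit_up = _resolve_situp_threshold(seq, cfg)
        calib = _calib.CalibrationResult(sit_up_threshold=sit_up)
        th_si = SitUpThresholds(
            sit_up_threshold=sit_up, sit_down_threshold=cfg.thresholds.situp.sit_down
        )
        labels = [situp_F(f, th_si) for f in features]

    warnings.extend(calib.warnings)
    spec = build_fsm(exercise, pullup_s1_down=cfg.fsm.pullup_s1_down)
    trace = fsm_run(spec, labels)
    return AssessmentResult(
        exercise=exercise,
        count=trace.count,
        calibration=calib,
        labels=labels,
        trace=trace,
        features=features,
        config_echo=cfg.to_dict(),
        warnings=warnings,
    )


@dataclass
class BatchItem:
    """Per-file outcome of a batch run: a result or an error message."""

    path: str
    result: Optional[AssessmentResult] = None
    error: Optional[str] = None


def assess_batch(
    paths: Sequence[str | Path], exercise: str, config: Optional[Config] = None
) -> List[BatchItem]:
    """Assess several session files independently; failures do not stop the batch."""
    cfg = config or Config()
    items: List[BatchItem] = []
    for p in paths:
        try:
            seq = read_keypoint_sequence(p, index_base=cfg.io.index_base)
            items.append(BatchItem(path=str(p), result=assess(seq, exercise, cfg)))
        except (PoseCountError, OSError) as exc:
            items.append(BatchItem(path=str(p), error=f"{type(exc).__name__}: {exc}"))
    return items


def counting_accuracy(
    detected: Sequence[int], ground_truth: Sequence[int]
) -> float:
    """Benchmark accuracy in percent: sum of detected counts (each capped at
    its session's ground truth) over the total ground-truth repetitions."""
    if len(detected) != len(ground_truth):
        raise ParameterError("detected and ground_truth must have equal length")
    total = sum(ground_truth)
    if total == 0:
        raise ParameterError("ground truth total is zero")
    credited = sum(min(d, g) for d, g in zip(detected, ground_truth))
    return 100.0 * credited / total
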