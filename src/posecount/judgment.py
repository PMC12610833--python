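"""Per-frame posture judgment functions F().

Each exercise has a judgment function mapping a frame's geometric features
to one of four posture labels: UP, DOWN, NULL, ERROR. The labels drive the
counting state machine; the functions themselves are stateless, total and
deterministic. Branch order matters and follows the assessment pseudocode
exactly; all comparisons are strict, so a feature sitting exactly on a
threshold falls through to the next branch.

Feature vocabulary (see :class:`FrameFeatures`):

* heights are image heights in pixels (frame height minus y);
* ``elbow_angle`` is the shoulder-elbow-hand joint angle;
* ``hip_angle`` the foot-hip-shoulder angle (body straightness);
* ``torso_angle`` the shoulder-foot-hand angle (torso vs. ground, vertex at
  the foot);
* ``body_horizontal_angle`` the acute angle of the hip->shoulder segment to
  the image horizontal (sit-up trunk inclination);
* ``elbow_knee_distance`` in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional

from .calibration import CalibrationResult
from .errors import MissingLandmarkError, ParameterError
from .geometry import (
    height_of,
    joint_angle,
    point_distance,
    segment_horizontal_angle,
)
from .model import KeypointSequence, Role, landmark_series


class PostureLabel(str, Enum):
    UP = "up"
    DOWN = "down"
    NULL = "null"
    ERROR = "error"


@dataclass
class PullUpThresholds:
    """Pull-up empirical constants. ``elbow_angle_threshold``: the elbows must
    be extended beyond this at the low position (default 150 degrees)."""

    elbow_angle_threshold: float = 150.0

    def __post_init__(self) -> None:
        if not (0.0 < self.elbow_angle_threshold < 180.0):
            raise ParameterError("elbow_angle_threshold must be in (0, 180)")


@dataclass
class PushUpThresholds:
    """Push-up constants: minimum elbow extension at the top (140 deg),
    maximum torso-ground angle at the bottom (15 deg), minimum hip angle for
    a straight body (140 deg). The mouth-down height threshold is calibrated
    per session (minimum shoulder height)."""

    elbow_extension_threshold: float = 140.0
    torso_angle_threshold: float = 15.0
    body_extension_threshold: float = 140.0

    def __post_init__(self) -> None:
        for name in ("elbow_extension_threshold", "torso_angle_threshold",
                     "body_extension_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 180.0):
                raise ParameterError(f"{name} must be in (0, 180), got {v}")


@dataclass
class SitUpThresholds:
    """Sit-up thresholds. ``sit_up_threshold`` is the elbow-knee distance (px)
    below which the athlete counts as sitting up; when left unset the
    pipeline derives it as half the session median torso length, making the
    default resolution-independent. ``sit_down_threshold`` is the maximum
    trunk-horizontal angle of the lying position (default 15 degrees)."""

    sit_up_threshold: Optional[float] = None
    sit_down_threshold: float = 15.0

    def __post_init__(self) -> None:
        if self.sit_up_threshold is not None and self.sit_up_threshold <= 0:
            raise ParameterError("sit_up_threshold must be positive")
        if self.sit_down_threshold <= 0:
            raise ParameterError("sit_down_threshold must be positive")


@dataclass
class FrameFeatures:
    """Geometric features of one frame; only the fields the exercise needs
    are populated."""

    mouth_height: Optional[float] = None
    eye_height: Optional[float] = None
    elbow_height: Optional[float] = None
    shoulder_height: Optional[float] = None
    elbow_angle: Optional[float] = None
    hip_angle: Optional[float] = None
    torso_angle: Optional[float] = None
    body_horizontal_angle: Optional[float] = None
    elbow_knee_distance: Optional[float] = None


_REQUIRED_ROLES = {
    "pullup": (Role.MOUTH, Role.EYE, Role.SHOULDER, Role.ELBOW, Role.HAND),
    "pushup": (Role.MOUTH, Role.SHOULDER, Role.ELBOW, Role.HAND, Role.HIP, Role.FOOT),
    "situp": (Role.SHOULDER, Role.ELBOW, Role.HIP, Role.KNEE),
}


def extract_features(
    seq: KeypointSequence, exercise: str, side_policy: str = "mean"
) -> List[FrameFeatures]:
    """Per-frame :class:`FrameFeatures` for one exercise.

    The sequence must be preprocessed and in pixel space; raises
    :class:`MissingLandmarkError` naming the role and exercise if a required
    landmark is absent.
    """
    if exercise not in _REQUIRED_ROLES:
        raise ParameterError(f"unknown exercise {exercise!r}")
    series = {}
    for role in _REQUIRED_ROLES[exercise]:
        try:
            series[role] = landmark_series(seq, role, side_policy)
        except MissingLandmarkError as exc:
            raise MissingLandmarkError(
                f"{exercise}: required landmark {role.value} missing ({exc})"
            ) from exc
    h = float(seq.height)
    out: List[FrameFeatures] = []
    for i in range(len(seq)):
        f = FrameFeatures()
        if exercise == "pullup":
            f.mouth_height = height_of(series[Role.MOUTH][i], h)
            f.eye_height = height_of(series[Role.EYE][i], h)
            f.elbow_height = height_of(series[Role.ELBOW][i], h)
            f.elbow_angle = joint_angle(
                series[Role.SHOULDER][i], series[Role.ELBOW][i], series[Role.HAND][i]
            )
        elif exercise == "pushup":
            f.mouth_height = height_of(series[Role.MOUTH][i], h)
            f.shoulder_height = height_of(series[Role.SHOULDER][i], h)
            f.elbow_angle = joint_angle(
                series[Role.SHOULDER][i], series[Role.ELBOW][i], series[Role.HAND][i]
            )
            f.hip_angle = joint_angle(
                series[Role.FOOT][i], series[Role.HIP][i], series[Role.SHOULDER][i]
            )
            f.torso_angle = joint_angle(
                series[Role.SHOULDER][i], series[Role.FOOT][i], series[Role.HAND][i]
            )
        else:  # situp
            f.elbow_knee_distance = point_distance(
                series[Role.ELBOW][i], series[Role.KNEE][i]
            )
            f.body_horizontal_angle = segment_horizontal_angle(
                series[Role.HIP][i], series[Role.SHOULDER][i]
            )
        out.append(f)
    return out


def pullup_F(
    f: FrameFeatures,
    calib: CalibrationResult,
    th: PullUpThresholds | None = None,
    per_frame_elbow: bool = False,
) -> PostureLabel:
    """Pull-up judgment: UP if the mouth clears the bar; DOWN if the eyes are
    below the eye-height threshold with the elbows extended; else NULL.

    By default the eye condition uses the calibrated (session-constant)
    eye-height threshold derived from the stable elbow height;
    ``per_frame_elbow=True`` restores the literal comparison against the
    frame's own elbow height.
    """
    if th is None:
        th = PullUpThresholds()
    if calib.bar_height is None or (calib.eye_height_threshold is None
                                    and not per_frame_elbow):
        raise ParameterError("pullup_F requires calibrated bar and eye thresholds")
    if f.mouth_height > calib.bar_height:
        return PostureLabel.UP
    eye_ref = f.elbow_height if per_frame_elbow else calib.eye_height_threshold
    if f.eye_height < eye_ref and f.elbow_angle > th.elbow_angle_threshold:
        return PostureLabel.DOWN
    return PostureLabel.NULL


def pushup_F(
    f: FrameFeatures,
    calib: CalibrationResult,
    th: PushUpThresholds | None = None,
) -> PostureLabel:
    """Push-up judgment. The straight-body check dominates: a hip angle below
    the body-extension threshold is ERROR regardless of anything else. Then
    UP on elbow extension; DOWN when the mouth is below the calibrated
    minimum shoulder height with the torso near the ground; else NULL."""
    if th is None:
        th = PushUpThresholds()
    if calib.mouth_down_threshold is None:
        raise ParameterError("pushup_F requires a calibrated mouth_down_threshold")
    if f.hip_angle < th.body_extension_threshold:
        return PostureLabel.ERROR
    if f.elbow_angle > th.elbow_extension_threshold:
        return PostureLabel.UP
    if (f.mouth_height < calib.mouth_down_threshold
            and f.torso_angle < th.torso_angle_threshold):
        return PostureLabel.DOWN
    return PostureLabel.NULL


def situp_F(f: FrameFeatures, th: SitUpThresholds) -> PostureLabel:
    """Sit-up judgment: UP when the elbow reaches the knee (distance below
    the sit-up threshold); DOWN when the trunk is near horizontal; else NULL.
    Never emits ERROR."""
    if th.sit_up_threshold is None:
        raise ParameterError("situp_F requires a resolved sit_up_threshold")
    if f.elbow_knee_distance < th.sit_up_threshold:
        return PostureLabel.UP
    if f.body_horizontal_angle < th.sit_down_threshold:
        return PostureLabel.DOWN
    return PostureLabel.NULL
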