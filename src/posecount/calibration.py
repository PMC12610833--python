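"""Data-derived threshold calibration via sliding-window variance plateaus.

The system is calibration-free in the camera sense: image-space quantities
such as the horizontal bar height have to be estimated from the keypoint
stream itself. The key observation is that once the athlete grips the bar,
the hand height stays constant; a sliding window whose sample variance is
below a bound marks such a stable plateau, and the maximum plateau mean is
taken as the bar height (Hmax). The same machinery applied to the elbow
height yields the eye-height threshold used by the pull-up judgment
function. For push-ups the only calibrated quantity is the session minimum
of the shoulder height, used as the mouth-down threshold.

Variance is the population variance (divide by the window size). The
variance bound defaults to 30, an empirical value expressed directly on the
variance (the field convention, even though variance is dimensionally px^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import EmptyInputError, MissingLandmarkError, NoStablePlateauError, ParameterError
from .geometry import height_of
from .model import KeypointSequence, Role, landmark_series


@dataclass
class PlateauParams:
    """Sliding-window stability detection parameters.

    ``window`` is the window size in frames (default 30, about one second at
    30 FPS); ``var_threshold`` the maximum acceptable window variance.
    """

    window: int = 30
    var_threshold: float = 30.0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ParameterError(f"plateau window must be >= 2, got {self.window}")
        if self.var_threshold <= 0:
            raise ParameterError("var_threshold must be positive")


@dataclass
class CalibrationResult:
    """Session-derived thresholds plus the stable windows that produced them."""

    bar_height: Optional[float] = None
    eye_height_threshold: Optional[float] = None
    mouth_down_threshold: Optional[float] = None
    sit_up_threshold: Optional[float] = None
    stable_windows: List[Tuple[int, float]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bar_height": self.bar_height,
            "eye_height_threshold": self.eye_height_threshold,
            "mouth_down_threshold": self.mouth_down_threshold,
            "sit_up_threshold": self.sit_up_threshold,
            "n_stable_windows": len(self.stable_windows),
            "warnings": list(self.warnings),
        }


def window_variance(series: Sequence[float], start: int, window: int) -> float:
    """Population variance of ``series[start : start + window]``."""
    x = np.asarray(series, dtype=float)
    if start < 0 or start + window > len(x):
        raise IndexError(
            f"window [{start}, {start + window}) out of bounds for length {len(x)}"
        )
    return float(np.var(x[start:start + window]))


def stable_plateau_max(
    series: Sequence[float], params: PlateauParams | None = None
) -> Tuple[float, List[Tuple[int, float]]]:
    """Maximum mean among variance-stable sliding windows.

    Slides a window of size ``params.window`` with stride 1; keeps windows
    with variance strictly below ``params.var_threshold``; returns the
    maximum window mean among kept windows and the kept ``(start, mean)``
    pairs. Raises :class:`NoStablePlateauError` if no window qualifies.
    """
    if params is None:
        params = PlateauParams()
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        raise EmptyInputError("stable_plateau_max: empty series")
    if len(x) < params.window:
        raise ParameterError(
            f"series length {len(x)} shorter than plateau window {params.window}"
        )
    sw = np.lib.stride_tricks.sliding_window_view(x, params.window)
    means = sw.mean(axis=1)
    variances = sw.var(axis=1)
    mask = variances < params.var_threshold
    if not mask.any():
        raise NoStablePlateauError(
            f"no window of {params.window} frames has variance < "
            f"{params.var_threshold} (min observed {variances.min():.1f})"
        )
    stable = list(zip(np.flatnonzero(mask).tolist(), means[mask].tolist()))
    return float(means[mask].max()), stable


def _height_series(seq: KeypointSequence, role: Role, side_policy: str) -> np.ndarray:
    pts = landmark_series(seq, role, side_policy)
    h = float(seq.height)
    return np.array([height_of(p, h) for p in pts])


def calibrate_pullup(
    seq: KeypointSequence,
    params: PlateauParams | None = None,
    side_policy: str = "mean",
) -> CalibrationResult:
    """Estimate bar height and eye-height threshold for a pull-up session.

    ``bar_height`` is the maximum stable-plateau mean of the hand height
    series (the hands are stationary whenever they grip the bar).
    ``eye_height_threshold`` is the maximum stable-plateau mean of the elbow
    height series - the stable elbow height once the athlete hangs from the
    bar, below which the eyes must descend for a valid low position.

    The input should already be preprocessed (corrected/smoothed) and in
    pixel space.
    """
    if params is None:
        params = PlateauParams()
    hands = _height_series(seq, Role.HAND, side_policy)
    elbows = _height_series(seq, Role.ELBOW, side_policy)
    bar, stable_h = stable_plateau_max(hands, params)
    eye_thr, _ = stable_plateau_max(elbows, params)
    result = CalibrationResult(
        bar_height=bar, eye_height_threshold=eye_thr, stable_windows=stable_h
    )
    # Plausibility: the bar should sit above the head for most of the session.
    try:
        eyes = _height_series(seq, Role.EYE, side_policy)
        if bar < float(np.median(eyes)):
            result.warnings.append(
                "bar_height below the session median eye height; the hands may "
                "never have reached a bar (standing-only session?)"
            )
    except MissingLandmarkError:
        pass
    return result


def calibrate_pushup(
    seq: KeypointSequence, side_policy: str = "mean"
) -> CalibrationResult:
    """Mouth-down threshold for push-ups: session minimum of the shoulder height."""
    shoulders = _height_series(seq, Role.SHOULDER, side_policy)
    return CalibrationResult(mouth_down_threshold=float(shoulders.min()))
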