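"""Inter-frame keypoint correction and sliding-window smoothing.

Pose estimators produce two characteristic error modes on video: sporadic
large displacements of a single landmark between consecutive frames ("flying
points") and small-amplitude frame-to-frame jitter. This module removes both
with a two-step pass over each landmark's coordinate series:

1. **Correction** - each frame is compared per-axis against the previous
   *corrected* frame; if either axis moves by more than a threshold (by
   default 1/30th of the frame width/height), the whole point is snapped back
   to the previous corrected position. A flying point is a 2D event, so both
   axes are aligned together.
2. **Smoothing** - a centered moving average (default 10 frames) over the
   corrected series; the window truncates (shrinks) at the sequence
   boundaries, introducing no phase shift and no padding. For even window
   sizes the window spans ``[i - W//2, i + W//2 - 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .errors import EmptyInputError, ParameterError, ValidationError
from .model import (
    CoordinateSpace,
    KeypointSequence,
    Point2D,
    sequence_from_arrays,
    sequence_to_arrays,
)


@dataclass
class PreprocessParams:
    """Correction/smoothing configuration.

    ``t_fraction`` is the correction threshold as a fraction of the frame
    dimension (per axis); ``window`` is the smoothing window size in frames.
    ``reference`` selects what frame i is compared against: the previous
    corrected frame (``"corrected"``, the in-place semantics of a sequential
    loop) or the previous raw frame (``"raw"``, for sensitivity studies).
    """

    t_fraction: float = 1.0 / 30.0
    window: int = 10
    reference: str = "corrected"

    def __post_init__(self) -> None:
        if not (0.0 < self.t_fraction < 1.0):
            raise ParameterError(f"t_fraction must be in (0, 1), got {self.t_fraction}")
        if self.window < 1:
            raise ParameterError(f"window must be >= 1, got {self.window}")
        if self.reference not in ("corrected", "raw"):
            raise ParameterError(f"reference must be 'corrected' or 'raw'")


def correct_interframe(
    series: Sequence[Point2D],
    t_x: float,
    t_y: float,
    reference: str = "corrected",
) -> List[Point2D]:
    """Snap large inter-frame displacements back to the previous position.

    Frame 0 is trusted unconditionally. For i >= 1, if |dx| > t_x or
    |dy| > t_y relative to the reference frame (previous corrected by
    default), the point is replaced by the previous *corrected* point.
    """
    if len(series) == 0:
        raise EmptyInputError("correct_interframe: empty series")
    if t_x <= 0 or t_y <= 0:
        raise ParameterError("correction thresholds must be positive")
    out: List[Point2D] = [Point2D(float(series[0][0]), float(series[0][1]))]
    for i in range(1, len(series)):
        cur = series[i]
        ref = out[i - 1] if reference == "corrected" else series[i - 1]
        if abs(cur[0] - ref[0]) > t_x or abs(cur[1] - ref[1]) > t_y:
            out.append(out[i - 1])
        else:
            out.append(Point2D(float(cur[0]), float(cur[1])))
    return out


def smooth_sliding(series: Sequence[Point2D], window: int) -> List[Point2D]:
    """Centered moving average per axis, truncated at the boundaries."""
    if len(series) == 0:
        raise EmptyInputError("smooth_sliding: empty series")
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    arr = np.asarray(series, dtype=float)
    sm = _smooth_array(arr, window)
    return [Point2D(float(x), float(y)) for x, y in sm]


def _smooth_array(arr: np.ndarray, window: int) -> np.ndarray:
    """Vectorized truncated centered mean over axis 0 of an (n, k) array."""
    n = arr.shape[0]
    lo = np.maximum(np.arange(n) - window // 2, 0)
    hi = np.minimum(np.arange(n) + (window - 1) // 2, n - 1)
    csum = np.vstack([np.zeros((1, arr.shape[1])), np.cumsum(arr, axis=0)])
    total = csum[hi + 1] - csum[lo]
    return total / (hi - lo + 1)[:, None]


def preprocess(seq: KeypointSequence, params: PreprocessParams | None = None,
               correct: bool = True, smooth: bool = True) -> KeypointSequence:
    """Apply correction then smoothing to every landmark series of a sequence.

    Thresholds are ``t_fraction * width`` and ``t_fraction * height``. The
    ``correct``/``smooth`` switches allow bypassing either step for
    diagnostics; with both off the sequence is returned unchanged.
    """
    if params is None:
        params = PreprocessParams()
    if not seq.frames:
        raise EmptyInputError("preprocess: empty sequence")
    if seq.space is not CoordinateSpace.PIXEL:
        raise ValidationError("preprocess requires a pixel-space sequence")
    arrays = sequence_to_arrays(seq)
    if not arrays:
        raise EmptyInputError("preprocess: no landmarks present in all frames")
    t_x = params.t_fraction * seq.width
    t_y = params.t_fraction * seq.height
    out = {}
    for key, arr in arrays.items():
        cur = arr
        if correct:
            pts = correct_interframe(
                [Point2D(x, y) for x, y in cur], t_x, t_y, reference=params.reference
            )
            cur = np.asarray(pts, dtype=float)
        if smooth:
            cur = _smooth_array(cur, params.window)
        out[key] = cur
    return sequence_from_arrays(
        out, seq.width, seq.height, fps=seq.fps,
        space=CoordinateSpace.PIXEL, indices=[f.index for f in seq.frames],
    )
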