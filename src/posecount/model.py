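"""Domain containers for per-frame human keypoint streams, plus readers/writers.

A session is an ordered sequence of frames; each frame carries the frame
dimensions and a mapping from landmark name (``ROLE_SIDE``, e.g.
``SHOULDER_LEFT``) to a 2D point. Coordinates are either normalized scale
factors in (0, 1) as emitted by pose estimators, or pixel coordinates in the
image coordinate system whose origin is the top-left corner with y pointing
down.

Two plain-text formats are supported:

* JSONL - one frame per line:
  ``{"index": 0, "width": 1920, "height": 1080, "space": "pixel",
  "landmarks": {"SHOULDER_LEFT": [x, y], ...}}``
* CSV - columns ``index,width,height,space`` followed by
  ``<ROLE>_<SIDE>_x, <ROLE>_<SIDE>_y`` pairs.

Landmark names outside the core vocabulary are preserved on read/write but
ignored by the assessment pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    MissingLandmarkError,
    OrderingError,
    SchemaError,
    ValidationError,
)


class Role(str, Enum):
    """Body landmark roles used by the assessment logic (BlazePose subset)."""

    MOUTH = "MOUTH"
    EYE = "EYE"
    SHOULDER = "SHOULDER"
    ELBOW = "ELBOW"
    HAND = "HAND"
    HIP = "HIP"
    KNEE = "KNEE"
    FOOT = "FOOT"


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class CoordinateSpace(str, Enum):
    NORMALIZED = "normalized"
    PIXEL = "pixel"


class Point2D(NamedTuple):
    """A 2D image point; y is downward-positive (origin at top-left)."""

    x: float
    y: float


def lm_key(role: Role | str, side: Side | str) -> str:
    """Canonical landmark name, e.g. ``lm_key(Role.HAND, Side.LEFT) == "HAND_LEFT"``."""
    role = Role(role).value if not isinstance(role, Role) else role.value
    side = Side(side).value if not isinstance(side, Side) else side.value
    return f"{role}_{side}"


#: Full core vocabulary (8 roles x 2 sides).
CORE_KEYS: Tuple[str, ...] = tuple(lm_key(r, s) for r in Role for s in Side)

#: Relative overshoot tolerated outside the nominal coordinate range before a
#: coordinate is rejected (pose estimators occasionally emit slightly
#: out-of-frame points).
OVERSHOOT_TOL = 0.05


@dataclass
class KeypointFrame:
    """One video frame's worth of detected landmarks."""

    index: int
    width: int
    height: int
    landmarks: Dict[str, Point2D]
    space: CoordinateSpace = CoordinateSpace.PIXEL


@dataclass
class KeypointSequence:
    """An ordered keypoint frame sequence (the raw or smoothed signal)."""

    frames: List[KeypointFrame]
    fps: float = 30.0

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def width(self) -> int:
        if not self.frames:
            raise EmptyInputError("sequence has no frames")
        return self.frames[0].width

    @property
    def height(self) -> int:
        if not self.frames:
            raise EmptyInputError("sequence has no frames")
        return self.frames[0].height

    @property
    def space(self) -> CoordinateSpace:
        if not self.frames:
            raise EmptyInputError("sequence has no frames")
        return self.frames[0].space

    def validate(self) -> "KeypointSequence":
        """Check container invariants; returns self for chaining."""
        if not self.frames:
            raise EmptyInputError("sequence has no frames")
        last = None
        w, h = self.frames[0].width, self.frames[0].height
        for fr in self.frames:
            if last is not None and fr.index <= last:
                raise OrderingError(
                    f"frame indices must be strictly increasing "
                    f"(index {fr.index} follows {last})"
                )
            last = fr.index
            if fr.width != w or fr.height != h:
                raise ValidationError(
                    f"frame {fr.index}: dimensions {fr.width}x{fr.height} differ "
                    f"from first frame {w}x{h}"
                )
            for key, pt in fr.landmarks.items():
                if not (np.isfinite(pt.x) and np.isfinite(pt.y)):
                    raise ValidationError(
                        f"frame {fr.index}: landmark {key} is not finite"
                    )
        return self


# ---------------------------------------------------------------------------
# construction helpers


def sequence_from_arrays(
    arrays: Dict[str, np.ndarray],
    width: int,
    height: int,
    fps: float = 30.0,
    space: CoordinateSpace = CoordinateSpace.PIXEL,
    indices: Optional[Sequence[int]] = None,
) -> KeypointSequence:
    """Build a sequence from ``{landmark: (n, 2) array}`` coordinate stacks."""
    n = len(next(iter(arrays.values())))
    if indices is None:
        indices = range(n)
    frames = []
    for row, idx in enumerate(indices):
        lms = {k: Point2D(float(a[row, 0]), float(a[row, 1])) for k, a in arrays.items()}
        frames.append(KeypointFrame(int(idx), width, height, lms, space))
    return KeypointSequence(frames, fps=fps)


def sequence_to_arrays(seq: KeypointSequence) -> Dict[str, np.ndarray]:
    """Inverse of :func:`sequence_from_arrays` for landmarks present in all frames."""
    keys = [k for k in seq.frames[0].landmarks if all(k in f.landmarks for f in seq.frames)]
    return {
        k: np.array([[f.landmarks[k].x, f.landmarks[k].y] for f in seq.frames], dtype=float)
        for k in keys
    }


# ---------------------------------------------------------------------------
# I/O


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise SchemaError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_keypoint_sequence(
    path: str | Path,
    format: Optional[str] = None,
    fps: float = 30.0,
    index_base: int = 0,
) -> KeypointSequence:
    """Read a keypoint sequence from a JSONL or CSV file.

    ``index_base`` declares the first frame number used by the producer
    (some tools number frames from 1); indices are shifted to be 0-based
    internally.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        frames = _read_jsonl(path)
    elif fmt == "csv":
        frames = _read_csv(path)
    else:
        raise SchemaError(f"unknown format {fmt!r}")
    if index_base:
        for fr in frames:
            fr.index -= index_base
    return KeypointSequence(frames, fps=fps).validate()


def _read_jsonl(path: Path) -> List[KeypointFrame]:
    frames: List[KeypointFrame] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"line {lineno}: invalid JSON ({exc})") from exc
            for fld in ("index", "width", "height", "space", "landmarks"):
                if fld not in rec:
                    raise SchemaError(f"frame record on line {lineno}: missing field {fld!r}")
            try:
                space = CoordinateSpace(rec["space"])
            except ValueError as exc:
                raise SchemaError(
                    f"frame {rec['index']}: unknown space {rec['space']!r}"
                ) from exc
            lms = {}
            for key, xy in rec["landmarks"].items():
                if not isinstance(xy, (list, tuple)) or len(xy) != 2:
                    raise SchemaError(f"frame {rec['index']}: landmark {key} must be [x, y]")
                lms[key] = Point2D(float(xy[0]), float(xy[1]))
            frames.append(
                KeypointFrame(int(rec["index"]), int(rec["width"]), int(rec["height"]), lms, space)
            )
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    return frames


def _read_csv(path: Path) -> List[KeypointFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    for fld in ("index", "width", "height", "space"):
        if fld not in df.columns:
            raise SchemaError(f"{path}: missing column {fld!r}")
    coord_cols = [c for c in df.columns if c.endswith(("_x", "_y"))]
    cols = list(df.columns)
    keys = sorted({c[:-2] for c in coord_cols}, key=lambda k: cols.index(f"{k}_x"))
    frames: List[KeypointFrame] = []
    for _, row in df.iterrows():
        lms = {}
        for key in keys:
            x, y = row[f"{key}_x"], row[f"{key}_y"]
            if pd.isna(x) or pd.isna(y):
                raise SchemaError(f"frame {int(row['index'])}: missing coordinate for {key}")
            lms[key] = Point2D(float(x), float(y))
        frames.append(
            KeypointFrame(
                int(row["index"]), int(row["width"]), int(row["height"]),
                lms, CoordinateSpace(row["space"]),
            )
        )
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    return frames


def write_keypoint_sequence(
    seq: KeypointSequence, path: str | Path, format: Optional[str] = None
) -> None:
    """Write a sequence to JSONL or CSV. Read∘write round-trips bit-identically."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for fr in seq.frames:
                rec = {
                    "index": fr.index,
                    "width": fr.width,
                    "height": fr.height,
                    "space": fr.space.value,
                    "landmarks": {k: [p.x, p.y] for k, p in fr.landmarks.items()},
                }
                fh.write(json.dumps(rec) + "\n")
    elif fmt == "csv":
        keys: List[str] = []
        for fr in seq.frames:
            for k in fr.landmarks:
                if k not in keys:
                    keys.append(k)
        rows = []
        for fr in seq.frames:
            row: Dict[str, object] = {
                "index": fr.index, "width": fr.width,
                "height": fr.height, "space": fr.space.value,
            }
            for k in keys:
                pt = fr.landmarks.get(k)
                row[f"{k}_x"] = pt.x if pt else np.nan
                row[f"{k}_y"] = pt.y if pt else np.nan
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise SchemaError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# coordinate conversion and bilateral aggregation


def to_pixel(seq: KeypointSequence) -> KeypointSequence:
    """Convert normalized scale factors to pixel coordinates.

    Each coordinate is multiplied by the frame width/height. Idempotent on
    sequences already in pixel space. Normalized coordinates outside (0, 1)
    by more than :data:`OVERSHOOT_TOL` raise :class:`ValidationError`.
    """
    if not seq.frames:
        raise EmptyInputError("sequence has no frames")
    if seq.space is CoordinateSpace.PIXEL:
        return seq
    frames = []
    for fr in seq.frames:
        lms = {}
        for key, pt in fr.landmarks.items():
            if not (-OVERSHOOT_TOL <= pt.x <= 1 + OVERSHOOT_TOL and
                    -OVERSHOOT_TOL <= pt.y <= 1 + OVERSHOOT_TOL):
                raise ValidationError(
                    f"frame {fr.index}: landmark {key} normalized coordinate "
                    f"({pt.x}, {pt.y}) outside (0, 1)"
                )
            lms[key] = Point2D(pt.x * fr.width, pt.y * fr.height)
        frames.append(
            KeypointFrame(fr.index, fr.width, fr.height, lms, CoordinateSpace.PIXEL)
        )
    return KeypointSequence(frames, fps=seq.fps)


def landmark_series(
    seq: KeypointSequence, role: Role | str, side_policy: str = "mean"
) -> List[Point2D]:
    """Per-frame points for one role under a bilateral aggregation policy.

    ``side_policy`` is ``"left"``, ``"right"``, or ``"mean"`` (coordinate-wise
    average of the two sides; the default, robust to single-side occlusion).
    """
    if seq.space is not CoordinateSpace.PIXEL:
        raise ValidationError("landmark_series requires a pixel-space sequence")
    if side_policy not in ("left", "right", "mean"):
        raise ValueError(f"unknown side_policy {side_policy!r}")
    role = Role(role)
    kl, kr = lm_key(role, Side.LEFT), lm_key(role, Side.RIGHT)
    out: List[Point2D] = []
    for fr in seq.frames:
        if side_policy == "left":
            pt = fr.landmarks.get(kl)
            if pt is None:
                raise MissingLandmarkError(f"frame {fr.index}: {kl} absent")
            out.append(pt)
        elif side_policy == "right":
            pt = fr.landmarks.get(kr)
            if pt is None:
                raise MissingLandmarkError(f"frame {fr.index}: {kr} absent")
            out.append(pt)
        else:
            pl, pr = fr.landmarks.get(kl), fr.landmarks.get(kr)
            if pl is None or pr is None:
                missing = kl if pl is None else kr
                raise MissingLandmarkError(f"frame {fr.index}: {missing} absent")
            out.append(Point2D((pl.x + pr.x) / 2.0, (pl.y + pr.y) / 2.0))
    return out
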