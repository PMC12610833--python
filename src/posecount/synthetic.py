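"""Ground-truthed synthetic keypoint sessions for the three exercises.

The generator replaces cameras and pose inference: it emits 30 FPS keypoint
trajectories for pull-ups, push-ups and sit-ups from piecewise-smooth
kinematic templates (cosine easing between posture keyframes), then overlays
the two error modes real pose streams exhibit - per-frame Gaussian jitter
and sporadic large-displacement "flying points". Every session comes with a
:class:`GroundTruth` record of the programmed repetitions, so end-to-end
counting accuracy can be measured exactly.

Templates are posture caricatures, not biomechanical simulation: each
exercise is a scripted cycle through the low and high postures whose
geometric features (heights, joint angles, distances) cross the assessment
thresholds exactly when a repetition is standard, and fail to cross them in
the programmed failure mode otherwise:

* pull-up - ``shallow_top`` (mouth never clears the bar), ``no_extension``
  (elbows never extend past 150 degrees at the bottom);
* push-up - ``hip_sag`` (hip angle dips below 140 degrees mid-rep),
  ``shallow_depth`` (the mouth never descends below the minimum shoulder
  height);
* sit-up - ``shallow_top`` (the elbow never reaches the knee).

Two deliberate pacing choices make the templates compatible with
inter-frame correction at its documented threshold (1/30th of the frame per
axis). First, genuine per-frame motion is kept below roughly one seventh of
the threshold, so the corrector re-acquires the trajectory even after
several consecutive flying points (a run of corrupted frames widens the gap
between the last trusted position and the next genuine one by one frame of
motion per corrupted frame). Second, sessions begin directly in the
exercise's starting posture (hanging, plank, lying) rather than with a
standing/mount transition: grabbing the bar is a fast gross displacement
that inter-frame correction cannot distinguish from an error, and it
carries no information for the decision logic under test.

All template coordinates are laid out on a 1920x1080 reference frame and
rescaled to the requested frame size. The first frame is never corrupted by
a flying point: the correction pass anchors on frame 0, and the error mode
being emulated is a transient mid-sequence detection failure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import SessionSpecError
from .model import (
    CoordinateSpace,
    KeypointSequence,
    Point2D,
    Role,
    Side,
    lm_key,
    sequence_from_arrays,
    sequence_to_arrays,
)

REF_W, REF_H = 1920.0, 1080.0

_FAILURE_MODES = {
    "pullup": ("none", "shallow_top", "no_extension"),
    "pushup": ("none", "hip_sag", "shallow_depth"),
    "situp": ("none", "shallow_top"),
}

#: Default repetition periods in frames (30 FPS): a deliberate, controlled
#: cadence of 2.7-4.7 s per rep, slow enough that genuine inter-frame motion
#: never approaches the flying-point correction threshold.
DEFAULT_PERIODS = {"pullup": 120, "pushup": 80, "situp": 140}


@dataclass
class NoiseParams:
    """Observation-noise model for synthetic keypoints.

    ``jitter_sigma`` - per-frame, per-axis Gaussian noise in pixels.
    ``flying_point_prob`` - per-landmark-frame probability of a large
    displacement of magnitude uniform in ``flying_point_range`` (fractions of
    the frame dimensions) at a uniform angle. Displaced points are clamped to
    the frame. All randomness flows through one generator seeded with
    ``seed``.
    """

    jitter_sigma: float = 2.0
    flying_point_prob: float = 0.02
    flying_point_range: Tuple[float, float] = (1.0 / 8.0, 1.0 / 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flying_point_prob <= 1.0):
            raise SessionSpecError("flying_point_prob must be in [0, 1]")
        lo, hi = self.flying_point_range
        if not (0.0 < lo <= hi < 1.0):
            raise SessionSpecError("flying_point_range must satisfy 0 < lo <= hi < 1")
        if self.jitter_sigma < 0:
            raise SessionSpecError("jitter_sigma must be >= 0")


@dataclass
class RepSpec:
    """One repetition: its period in frames (None = exercise default) and its
    failure mode."""

    period: Optional[int] = None
    failure_mode: str = "none"

    @property
    def standard(self) -> bool:
        return self.failure_mode == "none"


@dataclass
class SessionSpec:
    """A full synthetic session: exercise, repetitions, frame geometry."""

    exercise: str
    reps: List[RepSpec]
    width: int = 1920
    height: int = 1080
    fps: float = 30.0
    lead_in: int = 45
    lead_out: int = 30

    def __post_init__(self) -> None:
        if self.exercise not in _FAILURE_MODES:
            raise SessionSpecError(f"unknown exercise {self.exercise!r}")
        if not self.reps:
            raise SessionSpecError("a session needs at least one rep")
        for r in self.reps:
            if r.period is not None and r.period < 10:
                raise SessionSpecError(f"rep period {r.period} < 10 frames is infeasible")
            if r.failure_mode not in _FAILURE_MODES[self.exercise]:
                raise SessionSpecError(
                    f"failure mode {r.failure_mode!r} not defined for {self.exercise}"
                )

    @classmethod
    def standard(cls, exercise: str, n_reps: int, period: Optional[int] = None,
                 **kw) -> "SessionSpec":
        """A session of ``n_reps`` standard repetitions."""
        return cls(exercise=exercise,
                   reps=[RepSpec(period=period) for _ in range(n_reps)], **kw)

    @classmethod
    def with_failures(
        cls, exercise: str, n_standard: int, failures: Sequence[str],
        period: Optional[int] = None, **kw
    ) -> "SessionSpec":
        """``n_standard`` standard reps with failed reps interleaved evenly."""
        reps = [RepSpec(period=period) for _ in range(n_standard)]
        for i, mode in enumerate(failures):
            reps.insert((i * (len(reps) + 1)) // max(len(failures), 1),
                        RepSpec(period=period, failure_mode=mode))
        return cls(exercise=exercise, reps=reps, **kw)


@dataclass
class RepWindow:
    start: int
    end: int  # inclusive
    standard: bool
    failure_mode: str


@dataclass
class GroundTruth:
    """Programmed truth for one synthetic session.

    ``valid_rep_count`` is the number of repetitions the assessment standard
    credits: a credited rep is a valid low position (full extension for
    pull-ups, an error-free bottom for push-ups, lying flat for sit-ups)
    followed by a valid high position. For almost every session this equals
    the number of standard reps; the one exception is a bottom-valid-only
    attempt followed by a top-valid-only attempt (e.g. a shallow pull
    directly before a no-extension pull), which together complete exactly
    one valid low-to-high cycle and are credited as one.
    """

    exercise: str
    valid_rep_count: int
    reps: List[RepWindow]
    bar_height: Optional[float] = None
    bottom_shoulder_height: Optional[float] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "exercise": self.exercise,
            "valid_rep_count": self.valid_rep_count,
            "reps": [
                {"start": r.start, "end": r.end, "standard": r.standard,
                 "failure_mode": r.failure_mode}
                for r in self.reps
            ],
            "bar_height": self.bar_height,
            "bottom_shoulder_height": self.bottom_shoulder_height,
            "seed": self.seed,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# kinematic templates (reference frame 1920x1080; y down)

_PULL_BAR_Y = 180.0          # bar at image height 900
_PULL_X = 960.0
_PULL_HALF_ARM = 100.0       # upper arm = forearm = 100 px
_PULL_MOUTH_BOTTOM = 755.0   # mouth height hanging at the bottom
_PULL_MOUTH_TOP = 920.0      # standard top: clears the 900 px bar
_PULL_MOUTH_SHALLOW = 880.0  # shallow top: stays below the bar
_PULL_THETA_TOP = 60.0
_PULL_THETA_NOEXT = 130.0    # bottom elbow angle without full extension

_PUSH_HAND = (700.0, 1010.0)
_PUSH_FOOT = (1500.0, 1015.0)
_PUSH_HALF_ARM = 125.0
_PUSH_THETA_SPAN = 110.0     # elbow angle 180 (up) -> 70 (down)
_PUSH_SAG = 190.0            # hip drop producing a ~133 degree hip angle
_PUSH_SHALLOW_E = 0.55

_SIT_HIP = (960.0, 1000.0)
_SIT_KNEE = (1150.0, 950.0)
_SIT_FOOT = (1230.0, 1005.0)
_SIT_TORSO = 400.0
_SIT_ANGLE_DOWN = 2.0        # trunk-horizontal angle lying
_SIT_ANGLE_UP = 30.0
_SIT_EK_FAR = 300.0          # elbow-knee distance lying (arms crossed on chest)
_SIT_EK_NEAR = 30.0          # elbow-knee distance sat up
_SIT_SHALLOW_E = 0.25        # caps the distance at ~232 px, above the threshold

_SIDE_DX = 6.0               # left/right landmarks sit +-6 px of the midline

#: Standing-under-the-bar pose; not part of generated sessions (see module
#: docstring) but exported for degenerate-input studies such as a session in
#: which the hands never reach a bar.
PULL_STAND_POSE: Dict[Role, Tuple[float, float]] = {
    Role.FOOT: (960.0, 1040.0), Role.KNEE: (960.0, 890.0),
    Role.HIP: (960.0, 710.0), Role.SHOULDER: (960.0, 460.0),
    Role.ELBOW: (985.0, 590.0), Role.HAND: (990.0, 720.0),
    Role.EYE: (950.0, 345.0), Role.MOUTH: (950.0, 375.0),
}


def _arm_from_elbow_angle(theta_deg: float, half_arm: float) -> Tuple[float, float]:
    """Shoulder-hand distance and elbow lateral offset for an elbow angle."""
    d = math.sqrt(max(2.0 * half_arm**2 * (1.0 - math.cos(math.radians(theta_deg))), 0.0))
    ex = math.sqrt(max(half_arm**2 - (d / 2.0) ** 2, 0.0))
    return d, ex


def _pullup_hang_pose(e: float, mouth_top: float, theta_bottom: float) -> Dict[Role, Tuple[float, float]]:
    theta = theta_bottom + (_PULL_THETA_TOP - theta_bottom) * e
    d, ex = _arm_from_elbow_angle(theta, _PULL_HALF_ARM)
    hand = (_PULL_X, _PULL_BAR_Y)
    shoulder = (_PULL_X, _PULL_BAR_Y + d)
    elbow = (_PULL_X + ex, _PULL_BAR_Y + d / 2.0)
    mouth_h = _PULL_MOUTH_BOTTOM + (mouth_top - _PULL_MOUTH_BOTTOM) * e
    hip = (_PULL_X, shoulder[1] + 280.0)
    knee = (_PULL_X + 15.0, hip[1] + 165.0)
    foot = (_PULL_X + 15.0, knee[1] + 130.0)
    return {
        Role.HAND: hand, Role.SHOULDER: shoulder, Role.ELBOW: elbow,
        Role.MOUTH: (_PULL_X - 10.0, REF_H - mouth_h),
        Role.EYE: (_PULL_X - 10.0, REF_H - mouth_h - 30.0),
        Role.HIP: hip, Role.KNEE: knee, Role.FOOT: foot,
    }


def _pushup_pose(e: float, sag: float) -> Dict[Role, Tuple[float, float]]:
    theta = 180.0 - _PUSH_THETA_SPAN * e
    d, ex = _arm_from_elbow_angle(theta, _PUSH_HALF_ARM)
    hx, hy = _PUSH_HAND
    shoulder = (hx, hy - d)
    elbow = (hx - ex, hy - d / 2.0)
    fx, fy = _PUSH_FOOT
    hip = (shoulder[0] + 0.45 * (fx - shoulder[0]),
           shoulder[1] + 0.45 * (fy - shoulder[1]) + sag)
    knee = (hip[0] + 0.5 * (fx - hip[0]), hip[1] + 0.5 * (fy - hip[1]))
    return {
        Role.HAND: (hx, hy), Role.FOOT: (fx, fy), Role.SHOULDER: shoulder,
        Role.ELBOW: elbow, Role.HIP: hip, Role.KNEE: knee,
        Role.MOUTH: (590.0, shoulder[1] + 20.0),
        Role.EYE: (585.0, shoulder[1] - 10.0),
    }


def _situp_pose(e: float) -> Dict[Role, Tuple[float, float]]:
    a = math.radians(_SIT_ANGLE_DOWN + (_SIT_ANGLE_UP - _SIT_ANGLE_DOWN) * e)
    hx, hy = _SIT_HIP
    shoulder = (hx - _SIT_TORSO * math.cos(a), hy - _SIT_TORSO * math.sin(a))
    kx, ky = _SIT_KNEE
    dist = _SIT_EK_FAR + (_SIT_EK_NEAR - _SIT_EK_FAR) * e
    vx, vy = shoulder[0] - kx, shoulder[1] - ky
    norm = math.hypot(vx, vy)
    elbow = (kx + dist * vx / norm, ky + dist * vy / norm)
    return {
        Role.HIP: (hx, hy), Role.KNEE: (kx, ky), Role.FOOT: _SIT_FOOT,
        Role.SHOULDER: shoulder, Role.ELBOW: elbow,
        Role.HAND: (elbow[0] - 25.0, elbow[1] - 15.0),
        Role.MOUTH: (shoulder[0] - 20.0, shoulder[1] - 40.0),
        Role.EYE: (shoulder[0] - 25.0, shoulder[1] - 55.0),
    }


def _ease(t: float) -> float:
    """Cosine ease from 0 at t=0 to 1 at t=1."""
    return 0.5 * (1.0 - math.cos(math.pi * t))


def _segment_lengths(period: int, fractions: Sequence[float]) -> List[int]:
    lens = [max(int(round(period * f)), 1) for f in fractions[:-1]]
    last = period - sum(lens)
    if last < 1:
        raise SessionSpecError(f"rep period {period} too short for the template")
    return lens + [last]


def _period(rep: RepSpec, exercise: str) -> int:
    return rep.period if rep.period is not None else DEFAULT_PERIODS[exercise]


def _cycle(e_max: float, lengths: Sequence[int]) -> List[float]:
    """Elevation profile: hold, sweep, hold, sweep (starting at 0)."""
    a, rise, b, fall = lengths
    prof: List[float] = [0.0] * a
    prof.extend(e_max * _ease((j + 1) / rise) for j in range(rise))
    prof.extend([e_max] * b)
    prof.extend(e_max * (1.0 - _ease((j + 1) / fall)) for j in range(fall))
    return prof


def _pullup_params(rep: RepSpec) -> Tuple[float, float]:
    mouth_top = _PULL_MOUTH_SHALLOW if rep.failure_mode == "shallow_top" else _PULL_MOUTH_TOP
    theta_b = _PULL_THETA_NOEXT if rep.failure_mode == "no_extension" else 180.0
    return mouth_top, theta_b


def _pullup_frames(spec: SessionSpec) -> Tuple[List[Dict[Role, Tuple[float, float]]], List[RepWindow]]:
    """Pull-up session layout.

    A repetition's descent belongs to the repetition it arms: rep k is
    (descent from rep k-1's top, bottom hold, rise, top hold), so a
    ``no_extension`` failure keeps the elbows bent throughout its own
    descent and bottom, never producing a valid low position for its top.
    The session opens with a dead-hang lead-in at the first rep's bottom
    posture and closes with a standard descent and a bottom lead-out.
    """
    mouth0, theta0 = _pullup_params(spec.reps[0])
    poses: List[Dict[Role, Tuple[float, float]]] = (
        [_pullup_hang_pose(0.0, mouth0, theta0)] * spec.lead_in
    )
    windows: List[RepWindow] = []
    prev_mouth = mouth0
    for k, rep in enumerate(spec.reps):
        mouth_top, theta_b = _pullup_params(rep)
        p = _period(rep, "pullup")
        bottom = max(int(round(0.08 * p)), 1)
        top = max(int(round(0.05 * p)), 1)
        if p - bottom - top < 2:
            raise SessionSpecError(f"rep period {p} too short for the template")
        rise = (p - bottom - top) // 2
        fall = p - bottom - top - rise
        start = len(poses)
        if k > 0:  # descent from the previous top, at this rep's extension
            for j in range(fall):
                e = 1.0 - _ease((j + 1) / fall)
                poses.append(_pullup_hang_pose(e, prev_mouth, theta_b))
        poses.extend([_pullup_hang_pose(0.0, mouth_top, theta_b)] * bottom)
        for j in range(rise):
            poses.append(_pullup_hang_pose(_ease((j + 1) / rise), mouth_top, theta_b))
        poses.extend([_pullup_hang_pose(1.0, mouth_top, theta_b)] * top)
        windows.append(RepWindow(start, len(poses) - 1, rep.standard, rep.failure_mode))
        prev_mouth = mouth_top
    for j in range(48):  # closing descent, fully extended
        poses.append(_pullup_hang_pose(1.0 - _ease((j + 1) / 48), prev_mouth, 180.0))
    poses.extend([_pullup_hang_pose(0.0, _PULL_MOUTH_TOP, 180.0)] * spec.lead_out)
    return poses, windows


def _pushup_frames(spec: SessionSpec) -> Tuple[List[Dict[Role, Tuple[float, float]]], List[RepWindow]]:
    up = _pushup_pose(0.0, 0.0)
    poses: List[Dict[Role, Tuple[float, float]]] = [up] * spec.lead_in
    windows: List[RepWindow] = []
    for rep in spec.reps:
        e_max = _PUSH_SHALLOW_E if rep.failure_mode == "shallow_depth" else 1.0
        p = _period(rep, "pushup")
        descend, bottom, rise, top = _segment_lengths(p, (0.4, 0.1, 0.4, 0.1))
        start = len(poses)
        profile = _cycle(e_max, (0, descend, bottom, rise))
        profile.extend([0.0] * top)
        for k, e in enumerate(profile):
            sag = 0.0
            if rep.failure_mode == "hip_sag":
                phase = (k + 1) / len(profile)
                if 0.1 <= phase <= 0.9:
                    sag = _PUSH_SAG * 0.5 * (1.0 - math.cos(2.0 * math.pi * (phase - 0.1) / 0.8))
            poses.append(_pushup_pose(e, sag))
        windows.append(RepWindow(start, len(poses) - 1, rep.standard, rep.failure_mode))
    poses.extend([up] * spec.lead_out)
    return poses, windows


def _situp_frames(spec: SessionSpec) -> Tuple[List[Dict[Role, Tuple[float, float]]], List[RepWindow]]:
    down = _situp_pose(0.0)
    poses: List[Dict[Role, Tuple[float, float]]] = [down] * spec.lead_in
    windows: List[RepWindow] = []
    for rep in spec.reps:
        e_max = _SIT_SHALLOW_E if rep.failure_mode == "shallow_top" else 1.0
        p = _period(rep, "situp")
        rise, top, fall, bottom = _segment_lengths(p, (0.4, 0.1, 0.4, 0.1))
        start = len(poses)
        prof: List[float] = []
        prof.extend(e_max * _ease((j + 1) / rise) for j in range(rise))
        prof.extend([e_max] * top)
        prof.extend(e_max * (1.0 - _ease((j + 1) / fall)) for j in range(fall))
        prof.extend([0.0] * bottom)
        poses.extend(_situp_pose(e) for e in prof)
        windows.append(RepWindow(start, len(poses) - 1, rep.standard, rep.failure_mode))
    poses.extend([down] * spec.lead_out)
    return poses, windows


def _poses_to_sequence(
    poses: List[Dict[Role, Tuple[float, float]]], spec: SessionSpec
) -> KeypointSequence:
    sx, sy = spec.width / REF_W, spec.height / REF_H
    n = len(poses)
    arrays: Dict[str, np.ndarray] = {}
    for role in Role:
        base = np.array([poses[i][role] for i in range(n)], dtype=float)
        for side, dx in ((Side.LEFT, -_SIDE_DX), (Side.RIGHT, _SIDE_DX)):
            arr = base.copy()
            arr[:, 0] = (arr[:, 0] + dx) * sx
            arr[:, 1] = arr[:, 1] * sy
            arrays[lm_key(role, side)] = arr
    return sequence_from_arrays(
        arrays, spec.width, spec.height, fps=spec.fps, space=CoordinateSpace.PIXEL
    )


def _credited_reps(spec: SessionSpec) -> int:
    """Repetitions the assessment standard credits (see GroundTruth).

    Each rep contributes an ordered pair of events - a (possibly invalid)
    low position and a (possibly invalid) high position - and a credit is
    one valid low followed by a valid high; a push-up posture error voids
    the cycle in progress.
    """
    per_rep_events = {
        "none": "DU", "shallow_top": "D", "no_extension": "U",
        "hip_sag": "EU", "shallow_depth": "U",
    }
    armed = False
    count = 0
    for rep in spec.reps:
        for ev in per_rep_events[rep.failure_mode]:
            if ev == "D":
                armed = True
            elif ev == "E":
                armed = False
            else:  # U
                count += int(armed)
                armed = False
    return count


def generate_session(
    spec: SessionSpec, noise: Optional[NoiseParams] = None
) -> Tuple[KeypointSequence, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    The clean kinematic template is deterministic; noise (if given) is fully
    reproducible from ``noise.seed``.
    """
    builders = {"pullup": _pullup_frames, "pushup": _pushup_frames, "situp": _situp_frames}
    poses, windows = builders[spec.exercise](spec)
    seq = _poses_to_sequence(poses, spec)
    sy = spec.height / REF_H
    gt = GroundTruth(
        exercise=spec.exercise,
        valid_rep_count=_credited_reps(spec),
        reps=windows,
        seed=noise.seed if noise is not None else None,
    )
    if spec.exercise == "pullup":
        gt.bar_height = (REF_H - _PULL_BAR_Y) * sy
    elif spec.exercise == "pushup":
        d_bottom, _ = _arm_from_elbow_angle(180.0 - _PUSH_THETA_SPAN, _PUSH_HALF_ARM)
        gt.bottom_shoulder_height = (REF_H - (_PUSH_HAND[1] - d_bottom)) * sy
    if noise is not None:
        seq = inject_noise(seq, noise)
    return seq, gt


def standing_session(
    n_frames: int, width: int = 1920, height: int = 1080, fps: float = 30.0
) -> KeypointSequence:
    """A session of someone standing under the bar without ever mounting it
    (degenerate pull-up input: no high hand plateau exists)."""
    spec = SessionSpec("pullup", [RepSpec()], width=width, height=height)
    poses = [PULL_STAND_POSE] * n_frames
    return _poses_to_sequence(poses, spec)


def inject_noise(seq: KeypointSequence, noise: NoiseParams) -> KeypointSequence:
    """Overlay Gaussian jitter and sporadic flying points on a pixel sequence.

    A flying point displaces the landmark by ``(m*width*cos(phi),
    m*height*sin(phi))`` with magnitude fraction ``m`` uniform in
    ``flying_point_range`` and angle ``phi`` uniform; results are clamped to
    the frame. Frame 0 is exempt from flying points (see module docstring).
    """
    rng = np.random.default_rng(noise.seed)
    arrays = sequence_to_arrays(seq)
    w, h = float(seq.width), float(seq.height)
    out: Dict[str, np.ndarray] = {}
    lo, hi = noise.flying_point_range
    for key in sorted(arrays):
        arr = arrays[key].copy()
        n = len(arr)
        if noise.jitter_sigma > 0:
            arr += rng.normal(0.0, noise.jitter_sigma, size=arr.shape)
        if noise.flying_point_prob > 0:
            fly = rng.random(n) < noise.flying_point_prob
            fly[0] = False
            idx = np.flatnonzero(fly)
            m = rng.uniform(lo, hi, size=len(idx))
            phi = rng.uniform(0.0, 2.0 * np.pi, size=len(idx))
            arr[idx, 0] += m * w * np.cos(phi)
            arr[idx, 1] += m * h * np.sin(phi)
        arr[:, 0] = np.clip(arr[:, 0], 0.0, w)
        arr[:, 1] = np.clip(arr[:, 1], 0.0, h)
        out[key] = arr
    return sequence_from_arrays(
        out, seq.width, seq.height, fps=seq.fps,
        space=CoordinateSpace.PIXEL, indices=[f.index for f in seq.frames],
    )
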