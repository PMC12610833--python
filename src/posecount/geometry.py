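"""2D joint geometry on image coordinates.

All operations work in the image coordinate system: origin at the top-left
corner, x rightward, y downward. "Height" therefore means frame height minus
y, so that a larger height is physically higher.

Angles are unsigned and reported in degrees in [0, 180]: the thresholds that
drive posture judgment are magnitudes, and arccos of a cosine cannot carry a
sign in 2D without an orientation convention the assessment logic never uses.
"""

from __future__ import annotations

import math

from .errors import DegenerateGeometryError
from .model import Point2D


def joint_angle(a: Point2D, b: Point2D, c: Point2D) -> float:
    """Angle ABC (at vertex ``b``) between skeletal vectors BA and BC, in degrees.

    Computed as ``degrees(arccos(BA.BC / (|BA| |BC|)))`` with the cosine
    clamped to [-1, 1] so near-collinear input cannot raise a domain error.
    """
    bax, bay = a[0] - b[0], a[1] - b[1]
    bcx, bcy = c[0] - b[0], c[1] - b[1]
    na = math.hypot(bax, bay)
    nc = math.hypot(bcx, bcy)
    if na == 0.0 or nc == 0.0:
        raise DegenerateGeometryError("joint_angle: zero-length skeletal vector")
    cos_t = (bax * bcx + bay * bcy) / (na * nc)
    cos_t = max(-1.0, min(1.0, cos_t))
    return math.degrees(math.acos(cos_t))


def point_distance(a: Point2D, b: Point2D) -> float:
    """Euclidean distance between two keypoints, in pixels."""
    return math.hypot(b[0] - a[0], b[1] - a[1])


def height_of(p: Point2D, frame_height: float) -> float:
    """Image-convention height of a keypoint: ``frame_height - y``.

    Larger is physically higher; a point at the bottom edge has height 0.
    """
    return float(frame_height) - p[1]


def segment_horizontal_angle(p: Point2D, q: Point2D) -> float:
    """Acute angle between segment pq and the image horizontal, in [0, 90] degrees."""
    dx, dy = q[0] - p[0], q[1] - p[1]
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("segment_horizontal_angle: coincident points")
    return math.degrees(math.atan2(abs(dy), abs(dx)))
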