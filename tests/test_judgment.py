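"""Posture judgment functions: branch traces, precedence, strict boundaries."""

import pytest

from posecount.calibration import CalibrationResult
from posecount.config import Config
from posecount.judgment import (
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
from posecount.model import (
    CoordinateSpace,
    KeypointFrame,
    KeypointSequence,
    Point2D,
    lm_key,
    Role,
    Side,
)

UP, DOWN, NULL, ERROR = (PostureLabel.UP, PostureLabel.DOWN,
                         PostureLabel.NULL, PostureLabel.ERROR)

PULL_CALIB = CalibrationResult(bar_height=900.0, eye_height_threshold=800.0)
PUSH_CALIB = CalibrationResult(mouth_down_threshold=180.0)


def pull_f(mouth=700, eye=760, elbow_angle=170, elbow_height=800):
    return FrameFeatures(mouth_height=mouth, eye_height=eye,
                         elbow_angle=elbow_angle, elbow_height=elbow_height)


def push_f(hip=175, elbow=80, mouth=150, torso=10):
    return FrameFeatures(hip_angle=hip, elbow_angle=elbow,
                         mouth_height=mouth, torso_angle=torso)


class TestPullupF:
    def test_mouth_over_bar_is_up(self):
        assert pullup_F(pull_f(mouth=910), PULL_CALIB) is UP

    def test_low_position_with_extended_elbows_is_down(self):
        assert pullup_F(pull_f(mouth=700, eye=760, elbow_angle=170), PULL_CALIB) is DOWN

    def test_bent_elbows_at_bottom_is_null(self):
        assert pullup_F(pull_f(eye=760, elbow_angle=120), PULL_CALIB) is NULL

    def test_up_branch_dominates_down(self):
        # satisfies both the UP and DOWN conditions; pseudocode order wins
        f = pull_f(mouth=950, eye=700, elbow_angle=170)
        assert pullup_F(f, PULL_CALIB) is UP

    def test_never_error(self):
        for f in (pull_f(), pull_f(mouth=950), pull_f(elbow_angle=10)):
            assert pullup_F(f, PULL_CALIB) is not ERROR

    def test_per_frame_elbow_mode(self):
        f = pull_f(eye=760, elbow_angle=170, elbow_height=750)
        assert pullup_F(f, PULL_CALIB) is DOWN                       # 760 < 800
        assert pullup_F(f, PULL_CALIB, per_frame_elbow=True) is NULL  # 760 >= 750

    def test_boundary_equalities_fall_through(self):
        th = PullUpThresholds()
        # mouth exactly at the bar: not UP; eye exactly at threshold: not DOWN
        assert pullup_F(pull_f(mouth=900.0, eye=800.0), PULL_CALIB, th) is NULL
        # elbow angle exactly 150: strict comparison, falls to NULL
        assert pullup_F(pull_f(eye=760, elbow_angle=150.0), PULL_CALIB, th) is NULL
        assert pullup_F(pull_f(eye=760, elbow_angle=150.0 + 1e-9), PULL_CALIB, th) is DOWN


class TestPushupF:
    def test_hip_sag_is_error_regardless(self):
        f = push_f(hip=120, elbow=170, mouth=50, torso=5)
        assert pushup_F(f, PUSH_CALIB) is ERROR

    def test_extended_elbows_is_up(self):
        assert pushup_F(push_f(elbow=160), PUSH_CALIB) is UP

    def test_low_position_is_down(self):
        assert pushup_F(push_f(elbow=80, mouth=150, torso=10), PUSH_CALIB) is DOWN

    def test_fall_through_null(self):
        assert pushup_F(push_f(elbow=80, mouth=250, torso=10), PUSH_CALIB) is NULL

    def test_error_iff_hip_below_threshold(self):
        th = PushUpThresholds()
        assert pushup_F(push_f(hip=139.999), PUSH_CALIB, th) is ERROR
        assert pushup_F(push_f(hip=140.0), PUSH_CALIB, th) is not ERROR

    def test_boundary_equalities_fall_through(self):
        th = PushUpThresholds()
        assert pushup_F(push_f(elbow=140.0, mouth=250), PUSH_CALIB, th) is NULL
        assert pushup_F(push_f(elbow=80, mouth=180.0, torso=10), PUSH_CALIB, th) is NULL
        assert pushup_F(push_f(elbow=80, mouth=150, torso=15.0), PUSH_CALIB, th) is NULL


class TestSitupF:
    TH = SitUpThresholds(sit_up_threshold=60.0, sit_down_threshold=15.0)

    def test_elbow_at_knee_is_up(self):
        f = FrameFeatures(elbow_knee_distance=20, body_horizontal_angle=70)
        assert situp_F(f, self.TH) is UP

    def test_lying_is_down(self):
        f = FrameFeatures(elbow_knee_distance=300, body_horizontal_angle=8)
        assert situp_F(f, self.TH) is DOWN

    def test_mid_motion_is_null(self):
        f = FrameFeatures(elbow_knee_distance=300, body_horizontal_angle=40)
        assert situp_F(f, self.TH) is NULL

    def test_up_branch_dominates(self):
        f = FrameFeatures(elbow_knee_distance=20, body_horizontal_angle=5)
        assert situp_F(f, self.TH) is UP

    def test_never_error_and_boundaries_strict(self):
        f = FrameFeatures(elbow_knee_distance=60.0, body_horizontal_angle=15.0)
        assert situp_F(f, self.TH) is NULL


class TestDefaultThresholdConstants:
    """The empirical constants are wired through the config bit-exactly."""

    def test_config_defaults(self):
        cfg = Config()
        assert cfg.thresholds.pullup.elbow_angle == 150.0
        assert cfg.thresholds.pushup.elbow_extension == 140.0
        assert cfg.thresholds.pushup.torso_angle == 15.0
        assert cfg.thresholds.pushup.body_extension == 140.0
        assert cfg.calibration.var_threshold == 30.0
        assert cfg.preprocess.t_fraction == 1.0 / 30.0
        assert cfg.preprocess.window == 10
        assert cfg.thresholds.situp.sit_down == 15.0

    def test_dataclass_defaults_match_config(self):
        assert PullUpThresholds().elbow_angle_threshold == 150.0
        th = PushUpThresholds()
        assert (th.elbow_extension_threshold, th.torso_angle_threshold,
                th.body_extension_threshold) == (140.0, 15.0, 140.0)


class TestExtractFeatures:
    def _frame(self, lms):
        d = {}
        for role, (x, y) in lms.items():
            for side, dx in ((Side.LEFT, -2), (Side.RIGHT, 2)):
                d[lm_key(role, side)] = Point2D(x + dx, y)
        return KeypointSequence([KeypointFrame(0, 1920, 1080, d, CoordinateSpace.PIXEL)])

    def test_straight_arm_hang_elbow_angle(self):
        seq = self._frame({
            Role.SHOULDER: (960, 400), Role.ELBOW: (960, 300), Role.HAND: (960, 200),
            Role.MOUTH: (960, 340), Role.EYE: (960, 310),
        })
        f = extract_features(seq, "pullup")[0]
        assert f.elbow_angle == pytest.approx(180.0, abs=1e-6)
        assert f.eye_height == pytest.approx(770.0)

    def test_mouth_height_from_y(self):
        seq = self._frame({
            Role.SHOULDER: (960, 400), Role.ELBOW: (960, 300), Role.HAND: (960, 200),
            Role.MOUTH: (960, 100), Role.EYE: (960, 80),
        })
        f = extract_features(seq, "pullup")[0]
        assert f.mouth_height == pytest.approx(980.0)

    def test_plank_hip_angle_collinear(self):
        seq = self._frame({
            Role.SHOULDER: (700, 760), Role.ELBOW: (700, 880), Role.HAND: (700, 1010),
            Role.MOUTH: (600, 780), Role.HIP: (1100, 874.75), Role.FOOT: (1500, 989.5),
        })
        f = extract_features(seq, "pushup")[0]
        assert f.hip_angle == pytest.approx(180.0, abs=1.0)

    def test_missing_role_names_role_and_exercise(self):
        seq = self._frame({Role.SHOULDER: (0, 0)})
        from posecount.errors import MissingLandmarkError

        with pytest.raises(MissingLandmarkError, match="pullup.*MOUTH|MOUTH.*pullup"):
            extract_features(seq, "pullup")
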