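# Methods

This note documents the models and procedures implemented in `posecount`,
the parameters that matter, what the synthetic test bed does and does not
emulate, and the design decisions taken where the assessment procedure is
genuinely underdetermined.

## Signal model and preprocessing

The input is an ordered sequence of frames, each carrying 2D positions for
a 16-landmark vocabulary (8 roles × left/right): mouth, eye, shoulder,
elbow, hand, hip, knee, foot. Coordinates are either normalized scale
factors in (0, 1) or pixels in the image frame (origin top-left, y down);
normalized input is converted by multiplying by the frame width/height.
Per-landmark confidences, if present in input files, are preserved but
unused.

Two error modes dominate video pose streams: *flying points* (sporadic
gross mislocalizations of a landmark for one or a few frames) and *jitter*
(small zero-mean frame-to-frame noise). Both are handled by a two-step pass
applied independently to each landmark's x/y series:

1. **Inter-frame correction.** Frame 0 is trusted. For frame i ≥ 1, if
   |Δx| > T_x or |Δy| > T_y relative to the previous *corrected* frame, the
   whole point is replaced by the previous corrected point. Thresholds
   default to 1/30 of the frame width and height. Replacing the whole point
   (not one axis) reflects that a flying point is a 2D event. A config
   switch (`preprocess.reference: raw`) compares against the previous raw
   frame instead, for sensitivity studies.
2. **Sliding-window smoothing.** A centered moving average with window
   W = 10 frames. At the sequence boundaries the window truncates
   (shrinks); there is no padding and no phase shift. For even W the window
   spans [i − W/2, i + W/2 − 1].

Correction semantics imply a known failure mode: if the *reference* itself
is wrong (a corrupted first frame) or if genuine motion exceeds T per
frame, the corrected trajectory freezes until the true trajectory returns
within T of the frozen point. This is intrinsic to the algorithm, not an
implementation artifact; the synthetic generator's pacing choices (below)
keep genuine motion far from T.

## Geometry

Joint angles use the arccos of the normalized dot product of the two
skeletal vectors at the vertex, clamped to [−1, 1] before arccos so
near-collinear configurations cannot raise domain errors; precision near
0°/180° is limited to ~1e-6 degrees by the conditioning of arccos. Angles
are unsigned in [0, 180]: every threshold in the assessment logic is a
magnitude, and a 2D signed convention would add an orientation dependence
nothing consumes. Heights follow the image convention
`height = frame_height − y` (larger = physically higher). The sit-up
trunk inclination is the acute angle of the hip→shoulder segment against
the image horizontal — the trunk is what distinguishes lying from sitting;
the segment choice is configurable in the feature extractor.

Feature definitions per exercise:

| feature | definition |
|---|---|
| elbow angle | shoulder → elbow → hand |
| hip angle (push-up) | foot → hip → shoulder |
| torso angle (push-up) | shoulder → foot → hand (vertex at the foot) |
| body–horizontal angle (sit-up) | hip→shoulder vs. horizontal |
| mouth/eye/shoulder/elbow heights | image-convention heights |
| elbow–knee distance (sit-up) | Euclidean, pixels |

Bilateral landmarks are aggregated with `io.side_policy` (default `mean`,
the coordinate-wise left/right average — symmetric and robust to
single-side occlusion noise; `left`/`right` select one side).

## Calibration (variance plateaus)

Quantities that depend on the camera geometry or the athlete are estimated
from the session itself:

* **Bar height (pull-up).** Whenever the hands grip the bar their height is
  constant. A window of ω = 30 frames (≈ 1 s at 30 FPS) slides with stride
  1 over the hand-height series; windows with population variance < 30 are
  stable; the bar height is the maximum stable-window mean. The variance
  bound 30 is an empirical constant expressed directly on the variance
  value. The window/divisor convention is ω samples with population divisor
  ω. If no window qualifies, assessment aborts with a diagnostic — there is
  no bar to measure against.
* **Eye-height threshold (pull-up).** The same plateau scan over the elbow
  height series; its maximum stable mean is the stable elbow height once
  the athlete hangs from the bar. The pull-up judgment compares the eye
  height against this *calibrated constant* rather than the frame's own
  elbow height: a per-frame comparison would make the low-position test
  depend on the very limb configuration it is testing.
  `calibration.eye_threshold_mode: per_frame` restores the literal
  per-frame reading.
* **Mouth-down threshold (push-up).** The session minimum of the shoulder
  height. The low position requires the mouth below this minimum.
* **Sit-up distance threshold.** No universal pixel value exists, so the
  default is 0.5 × the session median torso (shoulder–hip) length —
  resolution- and athlete-independent. The lying threshold is 15° of trunk
  inclination. Both are plain config values when the defaults do not fit.

Calibration is a pre-pass over the whole session (two-pass, offline
processing); per-frame labeling starts only after the thresholds exist. A
plausibility warning is attached when the estimated bar height lies below
the session median eye height (hands that never reached a bar).

## Judgment functions

Each exercise has a per-frame total function F(features) → {up, down,
null, error}, with branch order exactly as specified and strict
inequalities throughout (boundary equality falls through):

* **Pull-up:** up if mouth height > bar height; else down if eye height <
  eye-height threshold and elbow angle > 150°; else null. Never error.
* **Push-up:** error if hip angle < 140° (checked first — a sagging or
  piked body voids the frame regardless of anything else); else up if
  elbow angle > 140°; else down if mouth height < mouth-down threshold and
  torso angle < 15°; else null.
* **Sit-up:** up if elbow–knee distance < sit-up threshold; else down if
  trunk inclination < 15°; else null. Never error (the five-state
  machine's error column is therefore unreachable for sit-ups; it is kept
  for structural uniformity with push-ups).

## Counting state machines

States: S1 high, S2 exited-high, S3 exited-low, S4 low, S5 error
(five-state machines only). One label is consumed per frame; emissions are
1 only on (S3, up)→S1 and (S4, up)→S1. Consequences: re-entering the high
position without passing the low position never counts; an error diverts
to S5 and voids the cycle in progress; null frames never change the count
on their own (null-insertion invariance is property-tested).

Two genuinely open points and their resolutions:

* **(S1, down) in the pull-up machine.** Transition target S4 (a fast drop
  straight to the low position) is the default; S2 is available via
  `fsm.pullup_s1_down`. The two variants agree on any sequence in which a
  down label does not immediately follow a high state; they genuinely
  disagree on e.g. up,down,up (1 vs. 0) — the disagreement is frozen in a
  unit test rather than papered over.
* **Initial state.** S2 (neutral "exited high"). No worked sequence
  depends on it: the shipped fixtures yield identical counts from S1 or S2
  starts (tested).

## Synthetic session generator

The generator is the test bed standing in for real recorded sessions. Each
exercise is a piecewise-smooth kinematic template (cosine easing between
posture keyframes) laid out on a 1920×1080 reference frame and rescaled:

* **Pull-up.** Hands fixed at the bar (image height 900); the elbow angle
  runs 180° (dead hang) ↔ 60° (top); the mouth rises from height 755 to
  920 on a standard rep (crossing the 900 px bar), to 880 on a
  `shallow_top` rep; `no_extension` caps the bottom elbow angle at 130°.
  A repetition's descent belongs to the repetition it arms, so a
  no-extension rep never produces a valid low position of its own.
* **Push-up.** Plank with hands and feet fixed; elbow angle 180° ↔ 70°;
  the mouth rides 20 px below the shoulder, so at full depth it falls
  below the session minimum shoulder height; `shallow_depth` caps the
  depth at 55%; `hip_sag` drops the hip mid-rep to a ~133° hip angle.
* **Sit-up.** Trunk rotates about the hip from 2° to 30° of inclination;
  the elbow travels along the knee direction from 300 px to 30 px of
  elbow–knee distance (arms-crossed style); `shallow_top` caps the travel
  at 25% (distance ≥ ~232 px, above the derived threshold).

Noise is overlaid per landmark: Gaussian jitter (default σ = 2 px) plus
flying points with per-landmark-frame probability 0.02 and displacement
magnitude uniform in [1/8, 1/4] of the frame dimensions at a uniform
angle, clamped to the frame. All randomness flows through a single seeded
generator; identical seeds give bit-identical sessions.

Three generator-design constraints are deliberate, and say something about
the correction algorithm's operating envelope rather than about the tested
logic:

1. **Pacing.** Default cadences (4 s pull-up, 2.7 s push-up, 4.7 s sit-up
   per rep) keep genuine per-frame motion below ≈ 5.5 px/frame vertically —
   about one seventh of the correction threshold — so the corrector
   re-acquires the true trajectory even after four consecutive flying
   points on the same landmark (each corrupted frame widens the reacquisition
   gap by one frame of genuine motion). At 2% corruption, runs of five
   or more are vanishingly rare at benchmark scale.
2. **No mount phase.** Sessions begin in the exercise's start posture
   (hang, plank, lying). Jumping up to grab the bar moves the hands many
   times faster than T per frame, which the correction step cannot
   distinguish from a flying point; it contributes nothing to the decision
   logic under test. A standing pose is still exported for degenerate-input
   studies (a session whose hands never reach a bar).
3. **Frame 0 is never corrupted.** The correction pass anchors on the
   first frame; a corrupted anchor freezes the whole series. The error mode
   being emulated is a transient mid-sequence detection failure.

What the generator does *not* emulate: perspective and camera pose, limb
self-occlusion (and the correlated, non-isotropic error it produces),
confidence-correlated noise, soft-tissue and clothing artifacts, multiple
people, or natural tempo variability. Passing tests therefore demonstrate
the correctness and noise-robustness of the decision logic under the
stated error model, not pose-estimation quality on real video.

**Ground truth.** `valid_rep_count` encodes the assessment standard the
state machine formalizes: a credited repetition is a valid low position
followed by a valid high position, with push-up posture errors voiding the
cycle in progress. For homogeneous failure modes this equals the number of
standard reps; a bottom-valid-only attempt directly followed by a
top-valid-only attempt (shallow pull, then no-extension pull) completes
one valid cycle between them and is credited as one — mirroring exactly
what a strict low→high reading of the counting rules credits.

## Benchmark and problem sizes

The synthetic counting benchmark uses five pull-up sessions with
{18, 22, 30, 35, 40} standard reps (145 total) and five push-up sessions
with {23, 34, 40, 45, 50} (192 total), default noise, one seed stream;
accuracy is 100 × Σ min(detected, truth) / Σ truth (per-session capping, so
overcounting cannot inflate the figure). The parameter-recovery suite
sweeps N = 1…20 for all three exercises under clean, noisy, and
noisy-without-correction conditions. These sizes run end to end in well
under a minute each on one CPU core and are the package's standard
regression scale.

## Numerical and degenerate-input choices

* Cosine clamping in `joint_angle`; coincident points raise a
  degenerate-geometry error rather than returning an arbitrary angle.
* Normalized coordinates may overshoot (0, 1) by up to 5% (estimator
  error) before conversion refuses them.
* Plateau scan: stride 1; strict `<` against the variance bound; ties in
  the maximum mean are irrelevant (any maximizer gives the same value).
* Empty sequences, missing landmarks, non-monotone frame indices, unknown
  config keys: all rejected with specific exceptions; the CLI maps schema
  errors to exit 2 and a failed plateau calibration to exit 3.
* CSV I/O uses round-trip float parsing so write→read is bit-identical.

## Known limitations

* The correction step's freeze behavior under sustained fast motion (or a
  corrupted first frame) is inherited from the algorithm itself; real
  deployments with fast athletes would need a motion-adaptive threshold.
* Threshold constants (150°, 140°, 15°, variance bound 30) are empirical
  values for 1080p-class streams; other resolutions or camera geometries
  may need the config overrides.
* The sit-up thresholds have no published reference values; the defaults
  are this package's own, chosen to be scale-free, and should be validated
  against protocol video before real use.
* 2D image-plane geometry only: angles are projections, and assessment is
  viewpoint-dependent by construction.
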