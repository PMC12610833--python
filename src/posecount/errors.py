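"""Exception hierarchy for posecount.

Every error raised by the library derives from :class:`PoseCountError` so
callers (and the CLI) can separate domain failures from programming errors.
"""


class PoseCountError(Exception):
    """Base class for all posecount errors."""


class SchemaError(PoseCountError):
    """An input file does not conform to the documented JSONL/CSV schema."""


class OrderingError(SchemaError):
    """Frame indices are not strictly increasing."""


class ValidationError(PoseCountError):
    """A sequence violates a container invariant (coordinate range, size...)."""


class EmptyInputError(PoseCountError):
    """An operation received an empty series or sequence."""


class ParameterError(PoseCountError):
    """A parameter is outside its documented domain."""


class MissingLandmarkError(PoseCountError):
    """A landmark required by the requested operation is absent."""


class DegenerateGeometryError(PoseCountError):
    """Coincident points where a direction or angle is required."""


class NoStablePlateauError(PoseCountError):
    """No sliding window satisfied the variance-stability condition.

    Raised during calibration; assessment of the session cannot proceed
    because a data-derived threshold (e.g. the bar height) does not exist.
    """


class SessionSpecError(PoseCountError):
    """A synthetic session specification is infeasible."""


class InvalidLabelError(PoseCountError):
    """A posture label outside the machine's input alphabet was supplied."""
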