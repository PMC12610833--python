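"""Finite-state repetition counting.

The counting machine has five states:

* S1 - high position (pulled up / top of push-up / sat up)
* S2 - exited the high position
* S3 - exited the low position
* S4 - low position (dead hang / bottom / lying)
* S5 - misaligned (error) posture; push-up and sit-up machines only

A transition consumes one posture label per frame and optionally emits a
count. Only the completion of a full low-to-high cycle emits: the
transitions (S3, UP) -> S1 and (S4, UP) -> S1 carry emission 1, everything
else 0. Re-entering the high position without passing through the low
position therefore never counts, and (for the five-state machines) an ERROR
label diverts to S5, voiding the cycle in progress.

The pull-up machine's alphabet is {UP, DOWN, NULL}; the push-up and sit-up
machines share one transition table over {UP, DOWN, ERROR, NULL}. For the
pull-up machine the (S1, DOWN) cell is configurable between S4 (a fast drop
straight to the low position, the default) and S2; neither target emits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from .errors import EmptyInputError, InvalidLabelError, ParameterError
from .judgment import PostureLabel


class FSMState(str, Enum):
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    S4 = "S4"
    S5 = "S5"


Transition = Tuple[FSMState, int]


@dataclass
class FSMSpec:
    """A counting machine: exercise name, transition map, initial state."""

    exercise: str
    transitions: Dict[Tuple[FSMState, PostureLabel], Transition]
    initial: FSMState = FSMState.S2


@dataclass
class AssessmentTrace:
    """Post-transition state and emission per consumed label."""

    states: List[FSMState]
    emissions: List[int]

    @property
    def count(self) -> int:
        return sum(self.emissions)


def build_fsm(exercise: str, pullup_s1_down: str = "s4") -> FSMSpec:
    """Construct the counting machine for an exercise.

    ``pullup_s1_down`` resolves the pull-up (S1, DOWN) cell: ``"s4"`` (fast
    drop to the low position, default) or ``"s2"``.
    """
    S1, S2, S3, S4, S5 = FSMState
    U, D, N, E = (PostureLabel.UP, PostureLabel.DOWN, PostureLabel.NULL,
                  PostureLabel.ERROR)
    if exercise == "pullup":
        if pullup_s1_down not in ("s2", "s4"):
            raise ParameterError(f"pullup_s1_down must be 's2' or 's4'")
        s1_down = S4 if pullup_s1_down == "s4" else S2
        t: Dict[Tuple[FSMState, PostureLabel], Transition] = {
            (S1, U): (S1, 0), (S1, D): (s1_down, 0), (S1, N): (S2, 0),
            (S2, U): (S1, 0), (S2, D): (S4, 0), (S2, N): (S2, 0),
            (S3, U): (S1, 1), (S3, D): (S4, 0), (S3, N): (S3, 0),
            (S4, U): (S1, 1), (S4, D): (S4, 0), (S4, N): (S3, 0),
        }
    elif exercise in ("pushup", "situp"):
        t = {
            (S1, U): (S1, 0), (S1, D): (S4, 0), (S1, E): (S5, 0), (S1, N): (S2, 0),
            (S2, U): (S1, 0), (S2, D): (S4, 0), (S2, E): (S5, 0), (S2, N): (S2, 0),
            (S3, U): (S1, 1), (S3, D): (S4, 0), (S3, E): (S5, 0), (S3, N): (S3, 0),
            (S4, U): (S1, 1), (S4, D): (S4, 0), (S4, E): (S5, 0), (S4, N): (S3, 0),
            (S5, U): (S1, 0), (S5, D): (S4, 0), (S5, E): (S5, 0), (S5, N): (S2, 0),
        }
    else:
        raise ParameterError(f"unknown exercise {exercise!r}")
    return FSMSpec(exercise=exercise, transitions=t, initial=FSMState.S2)


def fsm_step(spec: FSMSpec, state: FSMState, label: PostureLabel) -> Transition:
    """Pure table lookup: (state, label) -> (next state, emission)."""
    key = (state, label)
    if key not in spec.transitions:
        raise InvalidLabelError(
            f"{spec.exercise} machine has no transition for ({state.value}, "
            f"{label.value})"
        )
    return spec.transitions[key]


def fsm_run(spec: FSMSpec, labels: Sequence[PostureLabel]) -> AssessmentTrace:
    """Fold the machine over a label sequence from its initial state."""
    if len(labels) == 0:
        raise EmptyInputError("fsm_run: empty label sequence")
    state = spec.initial
    states: List[FSMState] = []
    emissions: List[int] = []
    for lab in labels:
        state, emit = fsm_step(spec, state, lab)
        states.append(state)
        emissions.append(emit)
    return AssessmentTrace(states=states, emissions=emissions)


_LETTER = {
    "U": PostureLabel.UP,
    "D": PostureLabel.DOWN,
    "N": PostureLabel.NULL,
    "E": PostureLabel.ERROR,
}


def parse_labels(text: str) -> List[PostureLabel]:
    """Parse a whitespace/comma-separated label string of U/D/N/E letters."""
    out = []
    for tok in text.replace(",", " ").split():
        if tok.upper() not in _LETTER:
            raise InvalidLabelError(f"unknown label letter {tok!r}")
        out.append(_LETTER[tok.upper()])
    return out


#: Worked assessment label sequences: each drives its machine through the
#: exact state walk of a small session (U=up, D=down, N=null, E=error).
#: F_PULL_B contains two re-entries to the high state without passing the low
#: position; F_PUSH_B contains an ERROR excursion to S5. Neither may count.
WORKED_FIXTURES = {
    "F_PULL_A": ("pullup", "D N U N " * 6),
    "F_PULL_B": ("pullup", "D N U N  D N U N  U N  U N  D N U N  D N U N"),
    "F_PUSH_A": ("pushup", "N D N U " * 9),
    "F_PUSH_B": ("pushup", "N D N U  N D N U  N D E N U  N D N U  N D N U"),
    "F_SIT_A": ("situp", "N D N U " * 7),
}


def write_trace_csv(
    trace: AssessmentTrace, labels: Sequence[PostureLabel], path: str | Path
) -> None:
    """Export a trace as CSV with columns step, label, state, emission."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "label", "state", "emission"])
        for i, (lab, st, em) in enumerate(zip(labels, trace.states, trace.emissions)):
            writer.writerow([i, lab.value, st.value, em])
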