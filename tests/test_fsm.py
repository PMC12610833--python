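"""Counting machine: worked fixtures, table cells, oracle equivalence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import armed_scan_count
from posecount.errors import EmptyInputError, InvalidLabelError, ParameterError
from posecount.fsm import (
    WORKED_FIXTURES,
    FSMState,
    build_fsm,
    fsm_run,
    fsm_step,
    parse_labels,
    write_trace_csv,
)
from posecount.judgment import PostureLabel

U, D, N, E = (PostureLabel.UP, PostureLabel.DOWN, PostureLabel.NULL, PostureLabel.ERROR)
S1, S2, S3, S4, S5 = FSMState

FIXTURE_COUNTS = {
    "F_PULL_A": 6, "F_PULL_B": 4, "F_PUSH_A": 9, "F_PUSH_B": 4, "F_SIT_A": 7,
}


class TestTransitionTables:
    @pytest.mark.parametrize(
        "state,label,expected",
        [
            (S3, U, (S1, 1)), (S4, U, (S1, 1)),  # the only counting cells
            (S2, U, (S1, 0)),                     # high re-entry never counts
            (S2, N, (S2, 0)),
            (S1, D, (S4, 0)),                     # fast drop straight to low
            (S4, N, (S3, 0)),
        ],
    )
    def test_pullup_cells(self, state, label, expected):
        spec = build_fsm("pullup")
        assert fsm_step(spec, state, label) == expected

    @pytest.mark.parametrize(
        "state,label,expected",
        [
            (S3, U, (S1, 1)), (S4, U, (S1, 1)),
            (S4, E, (S5, 0)), (S1, E, (S5, 0)),   # any error diverts to S5
            (S5, N, (S2, 0)), (S5, U, (S1, 0)),   # leaving S5 never counts
            (S2, D, (S4, 0)),
        ],
    )
    @pytest.mark.parametrize("exercise", ["pushup", "situp"])
    def test_five_state_cells(self, exercise, state, label, expected):
        spec = build_fsm(exercise)
        assert fsm_step(spec, state, label) == expected

    def test_emissions_only_on_low_to_high(self):
        for exercise in ("pullup", "pushup", "situp"):
            spec = build_fsm(exercise)
            emitting = {k for k, (_, e) in spec.transitions.items() if e == 1}
            assert emitting == {(S3, U), (S4, U)}

    def test_pullup_rejects_error_label(self):
        spec = build_fsm("pullup")
        with pytest.raises(InvalidLabelError):
            fsm_step(spec, S2, E)

    def test_unknown_exercise(self):
        with pytest.raises(ParameterError):
            build_fsm("plank")

    def test_initial_state_is_s2(self):
        assert build_fsm("pullup").initial is S2


class TestWorkedFixtures:
    @pytest.mark.parametrize("name", sorted(WORKED_FIXTURES))
    def test_fixture_counts(self, name):
        exercise, text = WORKED_FIXTURES[name]
        trace = fsm_run(build_fsm(exercise), parse_labels(text))
        assert trace.count == FIXTURE_COUNTS[name]

    def test_fixture_counts_independent_oracle(self):
        for name, (exercise, text) in WORKED_FIXTURES.items():
            labels = parse_labels(text)
            assert armed_scan_count(labels, exercise != "pullup") == FIXTURE_COUNTS[name]

    def test_counts_identical_from_s1_or_s2_start(self):
        for name, (exercise, text) in WORKED_FIXTURES.items():
            spec = build_fsm(exercise)
            labels = parse_labels(text)
            spec.initial = S1
            from_s1 = fsm_run(spec, labels).count
            spec.initial = S2
            assert from_s1 == fsm_run(spec, labels).count

    def test_state1_down_resolution_does_not_change_fixture_counts(self):
        for name, (exercise, text) in WORKED_FIXTURES.items():
            if exercise != "pullup":
                continue
            labels = parse_labels(text)
            prose = fsm_run(build_fsm("pullup", pullup_s1_down="s4"), labels).count
            table = fsm_run(build_fsm("pullup", pullup_s1_down="s2"), labels).count
            assert prose == table == FIXTURE_COUNTS[name]

    def test_state1_down_resolution_differs_on_drop_after_high(self):
        """The two readings of the (S1, DOWN) cell genuinely disagree when a
        DOWN immediately follows a high position: the fast-drop reading arms
        the next UP, the exit-to-S2 reading does not."""
        labels = parse_labels("U D U")
        assert fsm_run(build_fsm("pullup", pullup_s1_down="s4"), labels).count == 1
        assert fsm_run(build_fsm("pullup", pullup_s1_down="s2"), labels).count == 0


class TestRunProperties:
    def test_all_null_counts_zero(self):
        for exercise in ("pullup", "pushup", "situp"):
            trace = fsm_run(build_fsm(exercise), [N] * 50)
            assert trace.count == 0

    def test_trace_shapes(self):
        labels = parse_labels(WORKED_FIXTURES["F_PULL_A"][1])
        trace = fsm_run(build_fsm("pullup"), labels)
        assert len(trace.states) == len(trace.emissions) == len(labels)
        assert trace.count == sum(trace.emissions)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            fsm_run(build_fsm("pullup"), [])

    def test_random_suite_matches_oracle(self):
        """2000 random label sequences per machine agree with the independent
        armed-scan count (the full 10k-sequence suite runs in the acceptance
        checks)."""
        rng = random.Random(123)
        for exercise, alphabet in (("pullup", [U, D, N]),
                                   ("pushup", [U, D, N, E]),
                                   ("situp", [U, D, N, E])):
            spec = build_fsm(exercise)
            for _ in range(2000):
                labels = rng.choices(alphabet, k=rng.randint(1, 120))
                assert fsm_run(spec, labels).count == armed_scan_count(
                    labels, exercise != "pullup"
                )

    @given(st.lists(st.sampled_from([U, D, N, E]), min_size=1, max_size=80),
           st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_null_insertion_never_changes_count(self, labels, data):
        spec = build_fsm("pushup")
        base = fsm_run(spec, labels).count
        pos = data.draw(st.integers(0, len(labels)))
        k = data.draw(st.integers(1, 5))
        padded = labels[:pos] + [N] * k + labels[pos:]
        assert fsm_run(spec, padded).count == base

    def test_count_monotone_in_prefix(self):
        rng = random.Random(5)
        labels = rng.choices([U, D, N, E], k=150)
        spec = build_fsm("situp")
        counts = [fsm_run(spec, labels[: i + 1]).count for i in range(len(labels))]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_trace_csv_export(self, tmp_path):
        labels = parse_labels("D N U")
        trace = fsm_run(build_fsm("pullup"), labels)
        path = tmp_path / "trace.csv"
        write_trace_csv(trace, labels, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "step,label,state,emission"
        assert lines[3] == "2,up,S1,1"


def test_parse_labels_round_trip_and_errors():
    assert parse_labels("u,d N e") == [U, D, N, E]
    with pytest.raises(InvalidLabelError):
        parse_labels("U X")
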