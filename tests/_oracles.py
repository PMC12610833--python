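"""Independent brute-force oracles used by the test suite."""

from posecount.judgment import PostureLabel


def armed_scan_count(labels, five_state: bool) -> int:
    """Independent repetition-count oracle.

    A rep is credited at an UP label iff the athlete has been DOWN since the
    last UP (the machine can only be in S3/S4 then); an ERROR (five-state
    machines only) voids the cycle in progress. Deliberately implemented as
    a flag scan, not a state table, so it cannot share a bug with fsm_run.
    """
    armed = False
    count = 0
    for lab in labels:
        if lab is PostureLabel.UP:
            count += int(armed)
            armed = False
        elif lab is PostureLabel.DOWN:
            armed = True
        elif lab is PostureLabel.ERROR and five_state:
            armed = False
    return count
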