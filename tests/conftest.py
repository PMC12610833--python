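"""Shared fixtures: small synthetic sessions and an independent FSM oracle."""

from __future__ import annotations

import pytest

from posecount.synthetic import NoiseParams, SessionSpec, generate_session


@pytest.fixture(scope="session")
def pullup_clean():
    spec = SessionSpec.standard("pullup", 3)
    return generate_session(spec)


@pytest.fixture(scope="session")
def pullup_noisy():
    spec = SessionSpec.standard("pullup", 3)
    return generate_session(spec, NoiseParams(seed=11))


@pytest.fixture(scope="session")
def pushup_clean():
    spec = SessionSpec.standard("pushup", 3)
    return generate_session(spec)


@pytest.fixture(scope="session")
def situp_clean():
    spec = SessionSpec.standard("situp", 3)
    return generate_session(spec)
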