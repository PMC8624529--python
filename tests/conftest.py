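from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from acatpk.physiology import apply_rygb, default_fasted_physiology
from acatpk.scenarios import run_pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def fasted_physiology():
    return default_fasted_physiology()


@pytest.fixture
def rygb_physiology():
    return apply_rygb(default_fasted_physiology())


@pytest.fixture(scope="session")
def pipeline():
    """The full calibrated four-scenario run, shared across test modules."""
    return run_pipeline()
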