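"""Shared fixtures: small synthetic recordings and window stacks.

Everything is generated programmatically with fixed seeds; session scope
keeps the more expensive corpora to one construction per run.
"""

import numpy as np
import pytest

from imupipe.preprocessing import segment_windows, stack_windows
from imupipe.synthetic import ScenarioSpec, generate_recording


@pytest.fixture(scope="session")
def walking_recording():
    """30 s of 2 Hz walking on a street (audio + GPS present)."""
    return generate_recording(ScenarioSpec(activity="walking", location="street",
                                           duration_s=30.0, seed=42))


@pytest.fixture(scope="session")
def sitting_recording():
    return generate_recording(ScenarioSpec(activity="sitting", location="home",
                                           duration_s=30.0, seed=42))


@pytest.fixture(scope="session")
def walking_stacks(walking_recording):
    windows = segment_windows(walking_recording)
    return stack_windows(windows, rec=walking_recording)


@pytest.fixture(scope="session")
def sitting_stacks(sitting_recording):
    windows = segment_windows(sitting_recording)
    return stack_windows(windows, rec=sitting_recording)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
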