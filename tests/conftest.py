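import numpy as np
import pytest

import attngate as ag


@pytest.fixture(scope="session")
def calibration_plan() -> ag.SessionPlan:
    """The canonical 4-trial, 50 s + 50 s (400 s) calibration plan."""
    return ag.make_session_plan(4, 50.0, 50.0, seed=11)


@pytest.fixture(scope="session")
def calibration_stream(calibration_plan) -> ag.FrameStream:
    """Default-effect band-power session for the calibration plan."""
    return ag.synthesize_bandpower(calibration_plan)


@pytest.fixture(scope="session")
def trained_model(calibration_stream) -> ag.AttentionModel:
    return ag.train(calibration_stream)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
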