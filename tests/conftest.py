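import numpy as np
import pytest

from errpkit import preprocess, synthgen


@pytest.fixture(scope="session")
def small_session():
    """A short (2 min) default-world session with ground truth."""
    cfg = synthgen.SimulationConfig(duration_s=120.0, seed=7, snr_scale=2.0)
    rec, events, gt = synthgen.generate_recording(cfg)
    return rec, events, gt


@pytest.fixture(scope="session")
def clean_small(small_session):
    rec, events, _ = small_session
    return preprocess.run_pipeline(rec), events


@pytest.fixture(scope="session")
def small_trials(clean_small):
    rec, events = clean_small
    return preprocess.build_trialset(rec, events)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
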