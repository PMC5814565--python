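import numpy as np
import pytest
from hypothesis import settings

from pulsebeta import default_params, segment_beats, synthesize_record
from pulsebeta.synth import ProtocolSchedule

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rest_record():
    """60 s noiseless record at resting stiffness, with its ledger."""
    proto = ProtocolSchedule.constant(0.0, 60.0)
    record, ledger = synthesize_record(protocol=proto, sigma_bp=0.0, seed=11)
    return record, ledger


@pytest.fixture(scope="session")
def rest_beats(rest_record):
    """Beat windows of the rest record, anchored at the true onsets."""
    record, ledger = rest_record
    peaks = ledger["t0_sample"].to_numpy()
    return segment_beats(record, peaks)


@pytest.fixture(scope="session")
def truth():
    return default_params()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
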