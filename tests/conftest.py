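import numpy as np
import pytest

from ffrsws.preprocess import average, bandpass, clean, epoch
from ffrsws.simulate import (
    NeuralResponseModel,
    SessionProtocol,
    default_stimuli,
    simulate_session,
)

FS_EEG = 5000.0


@pytest.fixture(scope="session")
def stimuli():
    """The three preset SWS tokens at equal RMS (44.1 kHz)."""
    return default_stimuli()


@pytest.fixture(scope="session")
def stimulus(stimuli):
    return stimuli[0]  # 'baw'


def preprocess_session(session, **clean_kwargs):
    """filter -> epoch -> clean, shared by several test modules."""
    filt = bandpass(session.eeg, session.fs)
    return clean(epoch(filt, session.events, fs=session.fs), **clean_kwargs)


@pytest.fixture(scope="session")
def small_session(stimuli):
    """One small two-phase session with the default response model."""
    proto = SessionProtocol(reps_per_polarity=20, phases=("pre", "post"), training_gain=1.5)
    return simulate_session(stimuli, proto, NeuralResponseModel(), seed=42)


@pytest.fixture(scope="session")
def small_averages(small_session):
    ep = preprocess_session(small_session)
    return {
        phase: average(ep.select(phase=phase)) for phase in ("pre", "post")
    }
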