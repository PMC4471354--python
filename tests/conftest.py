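import numpy as np
import pandas as pd
import pytest

from attndecode.preprocess import EpochSet, preprocess_session
from attndecode.synth import SessionConfig, generate_session


def make_epochs(data, eog=None, labels=None, sfreq=256.0):
    """EpochSet straight from arrays, for unit tests of csp/decode/stats."""
    data = np.asarray(data, dtype=float)
    n_trials, _, T = data.shape
    if eog is None:
        eog = np.zeros((n_trials, 2, T))
    meta = pd.DataFrame({"trial_index": np.arange(n_trials)})
    return EpochSet(data=data, eog=np.asarray(eog, dtype=float),
                    labels=None if labels is None else np.asarray(labels, dtype=object),
                    trial_meta=meta, sfreq=sfreq, window=(-T / sfreq, T))


@pytest.fixture(scope="session")
def small_session():
    """52-trial session at 256 Hz: fast, with artifacts and planted truth."""
    cfg = SessionConfig(n_blocks=2, trials_per_block=26, sfreq=256.0,
                        artifact_fraction=0.1)
    return generate_session(cfg, seed=3)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    return preprocess_session(small_session)


@pytest.fixture(scope="session")
def decode_session():
    """160-trial strong-signal session at 256 Hz for decoding tests."""
    cfg = SessionConfig(n_blocks=4, trials_per_block=40, sfreq=256.0,
                        artifact_fraction=0.0)
    return generate_session(cfg, seed=5)


@pytest.fixture(scope="session")
def decode_epochs(decode_session):
    return preprocess_session(decode_session)
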