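import numpy as np
import pandas as pd
import pytest

from tripletseg.preprocess import EpochSet
from tripletseg.simulate import MontageSpec, SimulationConfig, make_montage, simulate_recording
from tripletseg.stimuli import build_lexicon, build_session_schedule


@pytest.fixture(scope="session")
def lexicon():
    return build_lexicon("A")


@pytest.fixture(scope="session")
def schedule(lexicon):
    return build_session_schedule(lexicon, seed=0)


@pytest.fixture(scope="session")
def montage16():
    # density-matched to the 128-channel default geometry
    return make_montage(16, head_radius=10.5 * np.sqrt(16 / 128), seed=0)


@pytest.fixture(scope="session")
def recording(schedule, montage16):
    """One clean full-session simulated recording shared across tests."""
    cfg = SimulationConfig(seed=7, word_rate_amplitude=4.0, learning_onset_s=0.0,
                           learning_ramp_s=0.001, pink_scale=10.0, white_scale=3.0)
    return simulate_recording(schedule, montage16, cfg)


def make_epochs(data, rate=300.0, tmin=0.0, metadata=None):
    data = np.asarray(data, float)
    n = data.shape[0]
    md = metadata if metadata is not None else pd.DataFrame(index=range(n))
    onsets = np.arange(n) * data.shape[2] / rate
    return EpochSet(data=data, sampling_rate=rate, onsets=onsets, metadata=md, tmin=tmin)


@pytest.fixture
def epoch_factory():
    return make_epochs
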