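import numpy as np
import pytest

from ioitrf import CVConfig, RecoveryParams, SimConfig
from ioitrf.features import binned_onset_matrix, make_uniform_bins
from ioitrf.simulate import simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """One 3-minute synthetic subject with default IOI-coupled amplitudes."""
    cfg = SimConfig(duration=180.0, seed=11)
    onsets, eeg = simulate_subject(cfg, RecoveryParams())
    return onsets, eeg


@pytest.fixture(scope="session")
def small_binned(small_subject):
    onsets, eeg = small_subject
    spec = make_uniform_bins(onsets.ioi[onsets.eligible], 5)
    feats = binned_onset_matrix(onsets, spec, eeg.fs, eeg.n_times)
    return feats, eeg, spec


@pytest.fixture
def cv_small():
    return CVConfig(n_segments=6)
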