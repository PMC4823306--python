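import numpy as np
import pytest

import sssepbci as s
from sssepbci.preprocess import build_trial_dataset, default_montage, reject_artifact_trials


@pytest.fixture(scope="session")
def patterns():
    return s.generate_twitch_patterns(rng_seed=1)


@pytest.fixture(scope="session")
def bci_session():
    """Small BCI session (2 runs, 60 trials) with default study conditions."""
    return s.simulate_session("bci", rng_seed=11, n_runs=2)


@pytest.fixture(scope="session")
def bci_dataset(bci_session):
    ds = build_trial_dataset(
        bci_session.recording, bci_session.schedule, bci_session.patterns,
        default_montage(),
    )
    return reject_artifact_trials(ds)


@pytest.fixture(scope="session")
def stim_freqs(bci_session):
    cfg = bci_session.config
    return (cfg.stim_freq_left, cfg.stim_freq_right)


@pytest.fixture(scope="session")
def clean_profile():
    """High-SNR profile for construction-oracle tests."""
    return s.SubjectProfile(noise_amp=1.0, alpha_amp=0.0)


@pytest.fixture(scope="session")
def null_profile():
    """No attention modulation, no blocking, no P300: class-independent EEG."""
    return s.SubjectProfile(attention_gain=1.0, blocking_depth_db=0.0, p300_amp=0.0)
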