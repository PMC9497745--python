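"""Shared fixtures: small synthetic subjects sized for fast unit tests."""

import numpy as np
import pytest

from entrofuse.preprocess import preprocess_subject
from entrofuse.synth import ClipProtocol, SynthConfig, generate_protocol, generate_subject


@pytest.fixture(scope="session")
def short_protocol():
    """Six balanced 4 s clips with short gaps — fast to synthesise."""
    return generate_protocol(6, seed=5, clip_s=4.0, hint_s=1.0, interval_s=2.0)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_subjects=2, n_channels=3, fs=1000.0, seed=11)


@pytest.fixture(scope="session")
def small_recording(short_protocol, small_config):
    return generate_subject(short_protocol, small_config, subject_seed=77,
                            subject_id="S00")


@pytest.fixture(scope="session")
def small_banded(small_recording, short_protocol):
    return preprocess_subject(small_recording, short_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
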