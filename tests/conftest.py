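"""Shared fixtures: small synthetic datasets, preprocessed recordings and
network inputs, generated once per session."""

import numpy as np
import pytest

from rfemotion import (NetworkInputTransformer, RadarConfig,
                       VitalSignProfile, default_emotion_profiles,
                       generate_dataset, preprocess_recording)


@pytest.fixture(scope="session")
def radar_config():
    return RadarConfig()


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free, artifact-free profile for deterministic signal checks."""
    return VitalSignProfile(rate_jitter_sd=0.0, noise_sd=0.0,
                            artifact_rate=0.0, artifact_amplitude=0.0)


@pytest.fixture(scope="session")
def small_dataset(radar_config):
    """4 subjects x 4 emotions, 150 s, with paired ECG."""
    return generate_dataset(default_emotion_profiles(), 4, 150.0,
                            radar_config, seed=11)


@pytest.fixture(scope="session")
def preprocessed(small_dataset):
    return [preprocess_recording(r) for r in small_dataset]


@pytest.fixture(scope="session")
def network_inputs(preprocessed):
    tf = NetworkInputTransformer(image_size=(32, 32))
    X_seq, X_img = tf.fit(preprocessed).transform(preprocessed)
    y = np.array([r.label for r in preprocessed])
    groups = np.array([r.subject_id for r in preprocessed])
    return X_seq, X_img, y, groups
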