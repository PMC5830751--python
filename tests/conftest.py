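import numpy as np
import pytest

import ethogram as e


@pytest.fixture(scope="session")
def small_dataset():
    """600 s of default synthetic data at 16 Hz (collar), fully labelled."""
    cfg = e.default_config(duration_s=600.0, fs=16.0, position="collar", seed=1)
    annotation = e.generate_bout_sequence(cfg)
    recording = e.synthesize_recording(annotation, cfg)
    return cfg, annotation, recording


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    cfg, annotation, recording = small_dataset
    return e.align(recording, annotation)


@pytest.fixture(scope="session")
def small_feature_table(small_samples):
    windows = e.segment(small_samples, 7.0)
    return e.features_table(windows, position="collar")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
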