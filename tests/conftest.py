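import numpy as np
import pytest

import accelflight as af
from accelflight import classify as cl


@pytest.fixture(scope="session")
def field_config():
    """Default field deployment: 23 Hz, 2 h, seed 42."""
    return af.SyntheticConfig(sample_rate=23.0, session_duration=7200.0, seed=42)


@pytest.fixture(scope="session")
def field_trace(field_config):
    return af.generate_trace(field_config)


@pytest.fixture(scope="session")
def aviary_training():
    """Aviary protocol: 30 min at 100 Hz, subsampled by 4 to 25 Hz,
    windowed with ground-truth labels."""
    cfg = af.SyntheticConfig(sample_rate=100.0, session_duration=1800.0, seed=11)
    trace, truth = af.generate_trace(cfg)
    tr25 = af.subsample(trace, 4)
    lab25 = truth.labels[::4]
    windows = cl.make_windows(tr25, 16)
    features = cl.extract_features(tr25, windows)
    labels = cl.window_true_labels(lab25, windows, tr25.sample_rate)
    return tr25, features, labels


@pytest.fixture(scope="session")
def aviary_model(aviary_training):
    _, features, labels = aviary_training
    return cl.train_classifier(features, labels.labels, seed=0)
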