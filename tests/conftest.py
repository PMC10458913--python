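import numpy as np
import pytest

from rdcnn_ecg import synthetic_ecg


@pytest.fixture(scope="session")
def clean_beats():
    """Small noise-free five-class dataset (20 beats/class, length 187)."""
    return synthetic_ecg.generate_dataset(
        {c: 20 for c in range(5)}, beat_length=187, spec=None, seed=11
    )


@pytest.fixture(scope="session")
def separable_features():
    """Two linearly separable 2-D clusters (centers +-5, radius 0.5, n=40)."""
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.5, size=(20, 2)) + [5.0, 5.0]
    b = rng.normal(0, 0.5, size=(20, 2)) + [-5.0, -5.0]
    feats = np.vstack([a, b])
    labels = np.array([0] * 20 + [1] * 20)
    return feats, labels
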