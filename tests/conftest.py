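import numpy as np
import pytest

from idcpheno import SyntheticCanopySpec, generate_canopy, sample_labeled_features


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticCanopySpec(
        width=128, height=128, canopy_radius=40, yellow_frac=0.30,
        brown_frac=0.10, n_debris=3, seed=42,
    )


@pytest.fixture(scope="session")
def canopy_image(small_spec):
    return generate_canopy(small_spec)


@pytest.fixture(scope="session")
def labeled_features():
    X, y = sample_labeled_features(800, seed=7)
    return X, y


def mask_precision_recall(pred: np.ndarray, truth: np.ndarray):
    tp = float((pred & truth).sum())
    return tp / max(pred.sum(), 1), tp / max(truth.sum(), 1)
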