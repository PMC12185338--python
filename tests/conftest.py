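import numpy as np
import pytest

from repalign import FeatureMatrix, PointEmbedding, rectify


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def features_20x8(rng):
    """Random rectified 20-object, 8-feature matrix."""
    return rectify(FeatureMatrix(rng.normal(size=(20, 8))))


@pytest.fixture
def embedding_12x5(rng):
    """Random non-negative 12-object, 5-dimension embedding."""
    return PointEmbedding(rng.exponential(0.8, size=(12, 5)))
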