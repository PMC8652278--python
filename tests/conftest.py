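import numpy as np
import pandas as pd
import pytest

from simcompare import SimilarityMatrix, euclidean_dissimilarity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, d, nonneg=True):
    """A random symmetric non-negative matrix (a valid dissimilarity)."""
    w = rng.uniform(size=(d, d))
    y = (w + w.T) / 2.0
    if not nonneg:
        y = y - y.mean()
    return y


def random_psd(rng, d, unit_norm=False):
    """Random symmetric PSD matrix with non-negative entries."""
    w = rng.uniform(size=(d, d))
    y = w @ w.T
    if unit_norm:
        y = y / np.linalg.norm(y, "fro")
    return y


@pytest.fixture
def feature_frame(rng):
    d, L = 15, 40
    return pd.DataFrame(
        rng.normal(size=(d, L)),
        index=[f"s{i}" for i in range(d)],
        columns=[f"f{j}" for j in range(L)],
    )


@pytest.fixture
def dissimilarity(feature_frame):
    return euclidean_dissimilarity(feature_frame)


@pytest.fixture
def small_similarity():
    values = np.array([[5.0, 2.0], [2.0, 7.0]])
    return SimilarityMatrix(values, ["a", "b"], kind="similarity")
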