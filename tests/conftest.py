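import numpy as np
import pytest

from snaresap import FeatureMatrix, FixtureSpec, PSSMProfile, generate_feature_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_profile():
    """Three positions 'ARA' with distinct integer scores."""
    return PSSMProfile(
        sequence_id="tiny",
        residues="ARA",
        scores=np.arange(60, dtype=float).reshape(3, 20),
    )


@pytest.fixture
def separable_matrix(rng):
    """Two well-separated Gaussian clusters, 30 per class, 5 features."""
    pos = rng.normal(5.0, 0.3, size=(30, 5))
    neg = rng.normal(-5.0, 0.3, size=(30, 5))
    X = np.vstack([pos, neg])
    y = np.array([1] * 30 + [-1] * 30)
    return FeatureMatrix(X=X, y=y, feature_ids=np.arange(5))


@pytest.fixture(scope="session")
def strong_signal_matrix():
    """100+100 PSSM-400 fixture with 10 informative cells at delta=3."""
    return generate_feature_matrix(FixtureSpec(n_pos=100, n_neg=100, delta=3.0, seed=11))
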