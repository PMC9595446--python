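import numpy as np
import pytest

from mldp.data_model import LabeledCohort


def make_cohort(X, y, prefix="s", provenance="test") -> LabeledCohort:
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    return LabeledCohort(
        sample_ids=tuple(f"{prefix}{i}" for i in range(len(y))),
        feature_names=tuple(f"f{j}" for j in range(X.shape[1])),
        X=X,
        y=y,
        provenance=provenance,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_cohort(rng):
    """Two well-separated 2-D classes, 40 samples."""
    n = 20
    X0 = rng.normal(0.0, 1.0, (n, 2))
    X1 = rng.normal(6.0, 1.0, (n, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    return make_cohort(X, y)


@pytest.fixture
def imbalanced_cohort(rng):
    """2-D overlapping classes, 30 majority / 10 minority."""
    X0 = rng.normal(0.0, 1.0, (30, 2))
    X1 = rng.normal(1.5, 1.0, (10, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 30 + [1] * 10)
    return make_cohort(X, y)
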