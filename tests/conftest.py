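import numpy as np
import pytest

from boxcoxopt import RangeScaler, SyntheticSpec, make_synthetic


@pytest.fixture(scope="session")
def two_cloud_data():
    """30 samples, 2 features, two well-separated clouds; range-standardized
    to [1, 2] so it can feed the Box-Cox criterion directly."""
    rng = np.random.default_rng(7)
    a = rng.normal([0.0, 0.0], 0.3, size=(15, 2))
    b = rng.normal([4.0, 4.0], 0.3, size=(15, 2))
    X = np.vstack([a, b])
    Y = np.repeat([0, 1], 15)
    order = rng.permutation(30)
    return RangeScaler().fit_transform(X[order]), Y[order]


@pytest.fixture(scope="session")
def overlapping_data():
    """30 samples in [1, 2] with class overlap, so the in-sample criterion
    actually varies over lambda."""
    rng = np.random.default_rng(11)
    a = rng.normal([0.0, 0.0], 1.0, size=(15, 2))
    b = rng.normal([1.2, 1.2], 1.0, size=(15, 2))
    X = np.vstack([a, b])
    Y = np.repeat([0, 1], 15)
    return RangeScaler().fit_transform(X), Y


@pytest.fixture(scope="session")
def half_circles_small():
    dm = make_synthetic(SyntheticSpec("half_circles", n_samples=80, seed=42))
    return dm.X, dm.Y
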