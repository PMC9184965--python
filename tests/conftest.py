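import numpy as np
import pytest

from waddyn import LandscapeModel, RiemannianMetric, make_family


@pytest.fixture(scope="session")
def cusp_family():
    return make_family("cusp1d")


@pytest.fixture(scope="session")
def dual_cusp_family():
    return make_family("dual_cusp1d")


@pytest.fixture(scope="session")
def flip_family():
    return make_family("elliptic_umbilic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_spd_metrics(seed: int, n: int, dim: int = 2):
    """Well-conditioned random SPD matrices for metric-invariance checks."""
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(n):
        a = rng.normal(size=(dim, dim))
        m = a @ a.T + dim * np.eye(dim)
        mats.append(m / np.linalg.norm(m, 2))
    return [RiemannianMetric.constant(m * 2.0) for m in mats]


@pytest.fixture(scope="session")
def flip_model(flip_family):
    return LandscapeModel(flip_family)
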