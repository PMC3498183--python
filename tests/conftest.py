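import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_triangles():
    """Two unit-weight triangles with no edges between them."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[a, b] = w[b, a] = 1.0
    return w


def random_weighted_graph(n, rng, density=1.0):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        w = w * mask
    w = np.triu(w, 1)
    return w + w.T


@pytest.fixture
def graph_factory():
    return random_weighted_graph
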