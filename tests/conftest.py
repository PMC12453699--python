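import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_clustered_instance(rng, n_max=40, d_max=3, with_noise=True):
    """A random labelled point set with >= 2 clusters of >= 2 members."""
    d = int(rng.integers(1, d_max + 1))
    k = int(rng.integers(2, 5))
    points, labels = [], []
    for c in range(k):
        size = int(rng.integers(2, max(3, n_max // k)))
        center = rng.uniform(-10, 10, d)
        points.append(center + rng.normal(0, rng.uniform(0.1, 1.5), (size, d)))
        labels.extend([c] * size)
    if with_noise and rng.random() < 0.5:
        n_noise = int(rng.integers(1, 5))
        points.append(rng.uniform(-20, 20, (n_noise, d)))
        labels.extend([-1] * n_noise)
    X = np.vstack(points)
    y = np.array(labels)
    perm = rng.permutation(X.shape[0])
    return X[perm], y[perm]


@pytest.fixture
def make_instance():
    return random_clustered_instance
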