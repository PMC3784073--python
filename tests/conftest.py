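import numpy as np
import pytest

from nbhnb import DiscreteDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_discrete_dataset(rng, n_samples=40, n_features=3, n_categories=3,
                            n_classes=2):
    """Small random categorical dataset with every class represented."""
    X = rng.integers(0, n_categories, size=(n_samples, n_features))
    y = rng.integers(0, n_classes, size=n_samples)
    y[:n_classes] = np.arange(n_classes)  # guarantee every class occurs
    return DiscreteDataset(X, y, n_categories=np.full(n_features, n_categories))


@pytest.fixture
def small_dataset(rng):
    return random_discrete_dataset(rng)
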