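import numpy as np
import pytest

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240511)


@pytest.fixture(scope="session")
def random_41mers(rng):
    return [random_seq(rng, 41) for _ in range(100)]


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated Gaussian blobs."""
    from sklearn.datasets import make_blobs

    X, y = make_blobs(n_samples=100, centers=2, cluster_std=0.5, random_state=0)
    return X, y
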