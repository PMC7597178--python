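import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from geme import WeightedNetwork, correlation_network

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_correlation_network(n: int, T: int, rng: np.random.Generator) -> WeightedNetwork:
    """Correlation network of random Gaussian data: a generic valid input."""
    return correlation_network(rng.standard_normal((n, T)))


@pytest.fixture
def random_net(rng):
    return random_correlation_network(12, 40, rng)


# ---------------------------------------------------------------- oracles

def brute_force_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """O(n^2) nested-loop Euclidean distances; independent of scipy."""
    k, n = coords.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for a in range(k):
                s += (coords[a, i] - coords[a, j]) ** 2
            D[i, j] = np.sqrt(s)
    return D


def brute_force_embedding_distances(W: np.ndarray, k: int) -> np.ndarray:
    """Distances of the spectral embedding, recomputed from first principles
    with an independent eigensolver (scipy.linalg.eigh on the explicitly
    constructed centered Gram matrix)."""
    from scipy.linalg import eigh

    n = W.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = 0.5 * (J @ W @ J)
    lam, V = eigh((B + B.T) / 2)
    order = np.argsort(lam)[::-1][:k]
    lam_k = np.clip(lam[order], 0.0, None)
    X = (np.sqrt(lam_k)[:, None]) * V[:, order].T
    return brute_force_distance_matrix(X)


def brute_force_k_function(coords, window, radii):
    """Uncorrected K estimate via the literal double loop over ordered pairs."""
    k, n = coords.shape
    lam = n / window.volume
    out = np.zeros(len(radii))
    for m, r in enumerate(radii):
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = np.sqrt(((coords[:, i] - coords[:, j]) ** 2).sum())
                if d < r:
                    count += 1
        out[m] = count / (lam * n)
    return out
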