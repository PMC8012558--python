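import numpy as np
import pytest

from riembci.geometry import SPDSet


def random_spd(rng: np.random.Generator, dim: int, scale: float = 1.0) -> np.ndarray:
    """A random SPD matrix: exp of a random symmetric matrix."""
    s = rng.standard_normal((dim, dim)) * scale
    s = 0.5 * (s + s.T)
    w, v = np.linalg.eigh(s)
    return (v * np.exp(w)) @ v.T


def random_invertible(rng: np.random.Generator, dim: int, scale: float = 0.5) -> np.ndarray:
    m = np.eye(dim) + scale * rng.standard_normal((dim, dim))
    while abs(np.linalg.det(m)) < 1e-3:
        m = np.eye(dim) + scale * rng.standard_normal((dim, dim))
    return m


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def spd_pairs(rng):
    """A batch of random SPD pairs (dim 4) for property checks."""
    return [(random_spd(rng, 4), random_spd(rng, 4)) for _ in range(25)]


@pytest.fixture
def labeled_spd_set(rng) -> SPDSet:
    """A small 2-class set of 3x3 SPD matrices."""
    mats, labels = [], []
    for k, c in enumerate("ab"):
        base = np.diag([2.0 + k, 1.0, 0.5 + k])
        for _ in range(10):
            j = random_invertible(rng, 3, 0.1)
            mats.append(j @ base @ j.T)
            labels.append(c)
    return SPDSet(np.array(mats), labels=np.array(labels))
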