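import numpy as np
import pytest

from mutualnet.io import InteractionMatrix, VisitRecord


def mk(w, scope="overall") -> InteractionMatrix:
    """InteractionMatrix from a plain array, with P*/B* labels."""
    w = np.asarray(w, dtype=np.int64)
    rows = tuple(f"P{i+1}" for i in range(w.shape[0]))
    cols = tuple(f"B{j+1}" for j in range(w.shape[1]))
    return InteractionMatrix(rows, cols, w, season_scope=scope)


@pytest.fixture
def identity2():
    return mk([[1, 0], [0, 1]])


@pytest.fixture
def ones2():
    return mk([[1, 1], [1, 1]])


@pytest.fixture
def records():
    return [
        VisitRecord("P1", "B1", 2, "rainy"),
        VisitRecord("P1", "B1", 3, "dry"),
        VisitRecord("P2", "B1", 1, "rainy"),
        VisitRecord("P2", "B2", 4, "dry"),
    ]


@pytest.fixture(scope="session")
def random_matrices():
    """Seeded pool of small random weighted matrices for property tests."""
    rng = np.random.default_rng(1234)
    pool = []
    for _ in range(12):
        n_r = rng.integers(2, 6)
        n_c = rng.integers(2, 6)
        w = rng.integers(0, 9, size=(n_r, n_c))
        if w.sum() == 0 or (w.sum(axis=1) == 0).any() or (w.sum(axis=0) == 0).any():
            w[:, 0] += 1
            w[0, :] += 1
        pool.append(mk(w))
    return pool
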