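import numpy as np
import pytest

from gensimpson import Community, SampleCounts


def random_simplex(rng: np.random.Generator, s: int) -> np.ndarray:
    """Dirichlet(1,..,1) point strictly inside the S-simplex."""
    while True:
        p = rng.dirichlet(np.ones(s))
        if np.all(p > 1e-6):
            # exact-sum guarantee for the strict constructor
            p = p / p.sum()
            return p


# fixed grid of small communities used by the exact-enumeration checks:
# for each S, a uniform vector plus skewed ones spanning even to dominated
ENUM_GRID = {
    2: [
        (0.5, 0.5),
        (0.6, 0.4),
        (2 / 3, 1 / 3),
        (0.8, 0.2),
        (0.95, 0.05),
    ],
    3: [
        (1 / 3, 1 / 3, 1 / 3),
        (0.5, 0.3, 0.2),
        (0.6, 0.3, 0.1),
        (0.7, 0.2, 0.1),
        (0.85, 0.1, 0.05),
    ],
}


@pytest.fixture(scope="session")
def enum_communities():
    return {
        s: [Community(np.array(p)) for p in vecs] for s, vecs in ENUM_GRID.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sample():
    return SampleCounts(np.array([2, 1]), labels=("A", "B"))
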