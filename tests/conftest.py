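import numpy as np
import pytest

from penphen.pedigree import Pedigree


def random_pedigree(rng: np.random.Generator, n: int, p_parent: float = 0.7) -> Pedigree:
    """Random valid pedigree: each animal's parents drawn among earlier animals."""
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(2, n):
        if rng.random() < p_parent:
            s, d = rng.choice(i, size=2, replace=False)
            sire[i], dam[i] = s, d
    return Pedigree(np.arange(1, n + 1), sire, dam)


def kinship_oracle(ped: Pedigree) -> np.ndarray:
    """Naive memoized kinship recursion; A = 2 * kinship."""
    from functools import lru_cache

    sire, dam = ped.sire, ped.dam

    @lru_cache(maxsize=None)
    def phi(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + phi(sire[i], dam[i]))
        if j > i:
            i, j = j, i
        # i is the younger: recurse on its parents
        return 0.5 * (phi(sire[i], j) + phi(dam[i], j))

    n = ped.n
    A = np.array([[2.0 * phi(i, j) for j in range(n)] for i in range(n)])
    return A


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
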