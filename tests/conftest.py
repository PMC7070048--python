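import numpy as np
import pytest

from uniopp import Landscape, fixture_landscape


@pytest.fixture
def collinear3() -> Landscape:
    """The canonical 3-zone collinear landscape (m = 5, 7, 11; O = 100)."""
    return fixture_landscape()


def make_random_landscape(
    n: int = 10, seed: int = 0, with_outflow: bool = False
) -> Landscape:
    """Seeded random planar landscape."""
    rng = np.random.default_rng(seed)
    return Landscape(
        zone_ids=np.array([f"z{k}" for k in range(n)]),
        coords=rng.uniform(0, 100, size=(n, 2)),
        m=rng.uniform(1, 50, size=n),
        outflow=rng.uniform(10, 1000, size=n) if with_outflow else None,
    )


@pytest.fixture
def random_landscape():
    """Factory fixture wrapping :func:`make_random_landscape`."""
    return make_random_landscape


def brute_force_sij(landscape: Landscape, d: np.ndarray, tie_policy: str = "strict"):
    """Independent double-loop oracle for intervening opportunities."""
    n = landscape.n_zones
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for k in range(n):
                if k in (i, j):
                    continue
                if d[i, k] < d[i, j]:
                    s[i, j] += landscape.m[k]
                elif tie_policy == "half" and d[i, k] == d[i, j]:
                    s[i, j] += landscape.m[k] / 2.0
    return s


def brute_force_probabilities(landscape: Landscape, d: np.ndarray, alpha: float, beta: float):
    """Term-by-term evaluation of the closed-form weight, then row
    normalisation -- fully independent of the package's vectorised path."""
    n = landscape.n_zones
    s = brute_force_sij(landscape, d)
    p = np.zeros((n, n))
    for i in range(n):
        q = np.zeros(n)
        for j in range(n):
            if j == i:
                continue
            mi, mj, sij = landscape.m[i], landscape.m[j], s[i, j]
            base = mi + (alpha + beta) * sij
            num = (mi + alpha * sij) * mj
            q[j] = num / (base * (base + mj))
        p[i] = q / q.sum()
    return p
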