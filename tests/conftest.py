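import numpy as np
import pytest

from eegdyn.network_metrics import WeightedGraph


@pytest.fixture
def two_triangles() -> WeightedGraph:
    """Two disconnected unit-weight triangles; optimal partition Q = 0.5."""
    w = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[i, j] = w[j, i] = 1.0
    return WeightedGraph(w)


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, maxl: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxl + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxl, lab))

    yield from rec(1, 0)


@pytest.fixture
def random_weighted_graph():
    """Factory for small random graphs with planted two-block structure."""

    def make(n: int, seed: int, p_within: float = 0.9, p_between: float = 0.15):
        rng = np.random.default_rng(seed)
        half = n // 2
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < half) == (j < half)
                p = p_within if same else p_between
                if rng.random() < p:
                    lo, hi = (0.5, 1.0) if same else (0.1, 0.4)
                    w[i, j] = w[j, i] = rng.uniform(lo, hi)
        return WeightedGraph(w)

    return make
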