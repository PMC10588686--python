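import numpy as np
import pytest

from dominet import AgonisticMatrix, SyntheticScenario, VisitationMatrix


@pytest.fixture
def chain_tournament():
    """A beats B, B beats C, A beats C, one contest each."""
    return AgonisticMatrix(list("ABC"), [[0, 1, 1], [0, 0, 1], [0, 0, 0]])


@pytest.fixture
def default_scenario():
    return SyntheticScenario(seed=0)


def random_tournament(rng: np.random.Generator, n: int) -> AgonisticMatrix:
    W = rng.integers(0, 6, size=(n, n)).astype(float)
    np.fill_diagonal(W, 0)
    # knock out some dyads entirely so the matrix is incomplete
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                W[i, j] = W[j, i] = 0
    if not np.any(W + W.T > 0):
        W[0, 1] = 1
    return AgonisticMatrix([f"s{k}" for k in range(n)], W)


def random_visitation(rng: np.random.Generator, n_r: int, n_c: int, scale: int = 8):
    A = rng.integers(0, scale + 1, size=(n_r, n_c))
    return VisitationMatrix(
        [f"r{i}" for i in range(n_r)], [f"c{j}" for j in range(n_c)], A
    )
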