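import numpy as np
import pytest

import lowrank_rnn as lr


@pytest.fixture
def rank_one_spec():
    """N=8 rank-one spec with mixed symmetry, stable (lambda = 0.6)."""
    return lr.build_rank_one(8, 2.0, 0.3, seed=1)


@pytest.fixture
def rank_two_spec():
    """N=40 rank-two spec, orthogonal-subspace parametrization."""
    return lr.build_low_rank(40, 2.0, rho_mn=[0.1, -0.3], seed=5)


def random_stable_spec(rng: np.random.Generator, N: int, rank: int):
    """Random stable spec: internal overlaps drawn so that all lambda^r < 1."""
    k = rng.uniform(0.5, 3.0)
    hi = min(1.0, 0.95 / k)
    rho = rng.uniform(-0.95, hi, size=rank)
    if rank == 1:
        return lr.build_rank_one(N, k, float(rho[0]), seed=int(rng.integers(2**31)))
    return lr.build_low_rank(N, k, rho_mn=rho, seed=int(rng.integers(2**31)))


def random_ensemble(rng: np.random.Generator, N: int, mode: str):
    seed = int(rng.integers(2**31))
    if mode == "intermediate":
        return lr.make_input(N, mode, C=int(rng.integers(2, max(3, N // 2))), seed=seed)
    return lr.make_input(N, mode, seed=seed)
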