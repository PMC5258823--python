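"""Shared fixtures: dense linear-system oracles.

The production code computes passage transforms by ladder recursions and
forward substitution; these oracles solve the same first-step linear
systems densely with ``numpy.linalg.solve`` on small grids, staying
independent of the recursion path they check.
"""

import numpy as np
import pytest

from clonofate.rates import ModelParams, build_ladder


def dense_expansion_lst(params: ModelParams, i_rho: int, s: float) -> np.ndarray:
    """Solve the tridiagonal first-step system for phi_{i,i_rho}(s) densely.

    Returns the full vector over start sizes 0..i_rho (boundaries 0 and 1).
    """
    ladder = build_ladder(params, i_rho)
    lam, mu = ladder.birth, ladder.death
    n = i_rho - 1
    A = np.zeros((n, n))
    b = np.zeros(n)
    for row, i in enumerate(range(1, i_rho)):
        A[row, row] = s + lam[i] + mu[i]
        if i - 1 >= 1:
            A[row, row - 1] = -mu[i]
        if i + 1 <= i_rho - 1:
            A[row, row + 1] = -lam[i]
        else:
            b[row] += lam[i]  # neighbour is the absorbing target, value 1
    phi = np.zeros(i_rho + 1)
    if n:
        phi[1:i_rho] = np.linalg.solve(A, b)
    phi[i_rho] = 1.0
    return phi


def dense_division_time_lst(params: ModelParams, i0: int, D: int, s: float) -> float:
    """Dense solve of the augmented (size, divisions) system at (i0, 0)."""
    ladder = build_ladder(params, i0 + D + 1)
    lam, mu = ladder.birth, ladder.death
    states = [(i, d) for d in range(D) for i in range(1, i0 + d + 1)]
    index = {sd: k for k, sd in enumerate(states)}
    n = len(states)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for (i, d), row in index.items():
        A[row, row] = s + lam[i] + mu[i]
        if (i - 1, d) in index:
            A[row, index[(i - 1, d)]] = -mu[i]
        if d + 1 == D:
            b[row] += lam[i]  # (i+1, D) is absorbing with value 1
        else:
            A[row, index[(i + 1, d + 1)]] = -lam[i]
    phi = np.linalg.solve(A, b)
    return float(phi[index[(i0, 0)]])


@pytest.fixture
def expansion_oracle():
    return dense_expansion_lst


@pytest.fixture
def division_time_oracle():
    return dense_division_time_lst


@pytest.fixture
def hard():
    """Factory for hard-niche parameter sets (no competition)."""
    def make(phi: float, mu: float = 1.0) -> ModelParams:
        return ModelParams(mu=mu, phi=phi)
    return make
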