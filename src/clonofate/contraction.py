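"""Time to contract to a smaller clonal size (including extinction).

Because extinction is certain, the time ``T_{i,i_rho}`` to shrink from
``i`` to ``i_rho < i`` is a proper random variable.  Its moments follow
the Karlin--McGregor series over the taboo ladder

    E[T^k_{i,i_rho}] = k sum_{n=i_rho}^{i-1} rho_n
                         sum_{j>n} E[T^{k-1}_{j,i_rho}] / (lambda_j rho_j),

with ``rho_{i_rho} = 1`` and ``rho_n = prod_{k=i_rho+1}^{n} mu_k/lambda_k``
(recovered from the global zeta ladder as ``zeta_n / zeta_{i_rho}``).  The
inner series converges factorially -- ``lambda_j`` is bounded by ``phi``
while ``mu_j = mu j`` grows -- so it is truncated adaptively once the next
term falls below ``tail_tol`` times the running sum.  All products are
accumulated in log space; in growth-favoured regimes the contraction time
from a large size is astronomically long yet still finite in log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import ModelParams, build_ladder

__all__ = ["ContractionMoments", "contraction_moments"]


@dataclass(frozen=True)
class ContractionMoments:
    """Moments ``E[T^k_{i,i_rho}]`` for all start sizes up to a cap.

    ``grid[k][i]`` holds the order-k moment from start ``i`` (zero at
    ``i = i_rho``); ``j_cap`` is the adaptive series cap actually used.
    """

    i_rho: int
    i_cap: int
    j_cap: int
    tail_tol: float
    log_grid: tuple  # index k = 0..k_max, arrays over 0..i_cap

    def moment(self, k: int, i: int) -> float:
        if not self.i_rho <= i <= self.i_cap:
            raise ValueError(f"start size {i} outside computed range")
        return float(np.exp(self.log_grid[k][i]))

    def mean(self, i: int) -> float:
        return self.moment(1, i)

    def sd(self, i: int) -> float:
        if len(self.log_grid) < 3:
            raise ValueError("second moment not computed; pass k_max >= 2")
        m1, m2 = self.moment(1, i), self.moment(2, i)
        return float(np.sqrt(max(m2 - m1**2, 0.0)))


def contraction_moments(params: ModelParams, i: int, i_rho: int,
                        k_max: int = 1, tail_tol: float = 1e-12) -> ContractionMoments:
    """Moments of the contraction time from ``i`` down to ``i_rho < i``.

    The grid is computed for every start size from ``i_rho`` up to the
    adaptive series cap (order k at one state consumes order k-1 at all
    larger states); results are independent of the cap once the tail rule
    is satisfied.  ``i_rho = 0`` gives the time to extinction.
    """
    if not 0 <= i_rho < i:
        raise ValueError("contraction needs 0 <= i_rho < i; "
                         "for growing targets use the expansion module")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    j_cap = max(2 * i + 16, i_rho + 32)
    hard_cap = max(100_000, 10 * i)
    while True:
        ladder = build_ladder(params, j_cap)
        with np.errstate(divide="ignore"):
            log_lam = np.log(ladder.birth)
        lrho = ladder.log_zeta - ladder.log_zeta[i_rho]  # log rho_n (n >= i_rho)

        grids = [np.zeros(j_cap + 1)]  # order 0: E[T^0] = 1 everywhere
        ok = True
        for k in range(1, k_max + 1):
            prev = grids[k - 1]
            j = np.arange(i_rho + 1, j_cap + 1)
            lt = prev[j] - log_lam[j] - lrho[j]  # log inner terms
            # tail rule on the widest inner sum (n = i_rho)
            lsum = np.logaddexp.reduce(lt)
            if lt[-1] > np.log(tail_tol) + lsum and j_cap < hard_cap:
                ok = False
                break
            # suffix sums S_n = sum_{j>n} exp(lt), n = i_rho..j_cap-1
            lS = np.logaddexp.accumulate(lt[::-1])[::-1]
            ln = lrho[i_rho:j_cap] + lS
            lacc = np.logaddexp.accumulate(ln)  # over n = i_rho..i-1
            grid_k = np.full(j_cap + 1, -np.inf)
            grid_k[i_rho + 1:] = np.log(k) + lacc
            grids.append(grid_k)
        if ok:
            break
        j_cap = min(2 * j_cap, hard_cap)

    # states right below the series cap see a truncated inner sum; only
    # expose starts up to the requested i, where the tail rule guarantees
    # the stated accuracy
    return ContractionMoments(i_rho=i_rho, i_cap=i, j_cap=j_cap,
                              tail_tol=tail_tol, log_grid=tuple(grids))
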