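"""Number of proliferation events before reaching a clonal size.

``N_{i,i_rho}`` counts the division (birth) events until the clonotype
first reaches size ``i_rho``; like the passage time it is defective, being
infinite on the extinction-first event, and ``P(N < inf) = v_{i,i_rho}``
(the counting variable is finite exactly when the size is reached).  The
module provides the pmf by a two-index recursion, restricted factorial
moments by the zeta-ladder recursion, the percentile-truncated factorial
moments of ``N_i^max`` (divisions to reach the maximum clonal size), and
conditional mean/sd summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .expansion import (RestrictedMoments, _log_prefix, _moment_log_grids,
                        percentile, xmax_distribution)
from .rates import ModelParams, RateLadder, build_ladder

__all__ = [
    "DivisionCountPMF",
    "division_count_pmf",
    "division_factorial_moments",
    "nmax_moments",
    "conditional_division_stats",
]


@dataclass(frozen=True)
class DivisionCountPMF:
    """pmf of the division count ``N_{i,i_rho}`` on a (start, count) grid.

    ``probs[i, j] = P(N_{i,i_rho} = j)``.  At least ``i_rho - i`` births are
    needed, so the pmf vanishes for ``j < i_rho - i``; the total mass from
    start ``i`` converges (upward) to the reach probability ``v_{i,i_rho}``
    as ``j_max`` grows.
    """

    i_rho: int
    j_max: int
    probs: np.ndarray  # shape (i_rho + 1, j_max + 1)

    def pmf(self, i: int, j: int) -> float:
        return float(self.probs[i, j]) if j <= self.j_max else 0.0


def division_count_pmf(params: ModelParams, i: int, i_rho: int,
                       j_max: Optional[int] = None, tol: float = 1e-8,
                       hard_cap: int = 1_000_000,
                       ladder: Optional[RateLadder] = None) -> DivisionCountPMF:
    """pmf of ``N_{i,i_rho}`` by the recursion ascending in (j, i).

    x~^j_i = mu_i/(lam_i+mu_i) x~^j_{i-1} + lam_i/(lam_i+mu_i) x~^{j-1}_{i+1}

    with boundaries x~^j_0 = 0 and x~^j_{i_rho} = [j == 0].  When ``j_max``
    is not given, the count cap grows until the missing restricted mass at
    the focal start ``i`` drops below ``tol`` (the mass limit is the reach
    probability ``v``), or a hard cap is hit.
    """
    if not 1 <= i <= i_rho:
        raise ValueError("need 1 <= i <= i_rho")
    if ladder is None or ladder.i_max < i_rho:
        ladder = build_ladder(params, i_rho)
    lam, mu = ladder.birth, ladder.death
    with np.errstate(divide="ignore", invalid="ignore"):
        pb = np.where(lam + mu > 0, lam / (lam + mu), 0.0)  # birth first
        pd = np.where(lam + mu > 0, mu / (lam + mu), 0.0)
    lpre = _log_prefix(ladder, i_rho)
    v_focus = 1.0 if i == i_rho else float(np.exp(lpre[i - 1] - lpre[i_rho - 1]))

    adaptive = j_max is None
    cap = j_max if j_max is not None else max(4 * (i_rho - i + 1), 16)
    cols = [np.zeros(i_rho + 1)]
    cols[0][i_rho] = 1.0  # j = 0
    total = np.zeros(i_rho + 1)
    total[:] = cols[0]
    j = 0
    while True:
        while j < cap:
            j += 1
            prev = cols[j - 1]
            cur = np.zeros(i_rho + 1)
            for ii in range(1, i_rho):
                cur[ii] = pd[ii] * cur[ii - 1] + pb[ii] * prev[ii + 1]
            cols.append(cur)
            total += cur
        if not adaptive or v_focus - total[i] < tol or cap >= hard_cap:
            break
        cap = min(2 * cap, hard_cap)
    probs = np.stack(cols, axis=1)
    return DivisionCountPMF(i_rho=i_rho, j_max=cap, probs=probs)


def division_factorial_moments(params: ModelParams, i: int, i_rho: int,
                               k_max: int,
                               ladder: Optional[RateLadder] = None) -> RestrictedMoments:
    """Restricted factorial moments ``E[N(N-1)...(N-k+1); N < inf]``.

    Same elimination structure as the passage-time moments, with the
    source term ``lambda_i k m~^(k-1)_{i+1}`` in place of ``k m^(k-1)_i``;
    order 0 is the reach probability.
    """
    if i_rho < 1 or k_max < 1:
        raise ValueError("need i_rho >= 1 and k_max >= 1")
    if not 0 <= i <= i_rho:
        raise ValueError("start size must satisfy 0 <= i <= i_rho")
    if ladder is None or ladder.i_max < i_rho:
        ladder = build_ladder(params, i_rho)
    grids = _moment_log_grids(ladder, i_rho, k_max, kind="divisions")
    return RestrictedMoments(i_rho=i_rho, k_max=k_max, log_m=tuple(grids))


def nmax_moments(params: ModelParams, i0: int, k_max: int = 1,
                 q_max: float = 0.99) -> np.ndarray:
    """Truncated factorial moments of ``N_i0^max`` (orders 1..k_max).

    Mirrors the percentile truncation used for the time to the maximum:
    ``sum_{i_rho=i0+1}^{K_qmax} m~^(k)_{i0,i_rho} (1 - v_{i_rho+1}/v_{i_rho})``.
    """
    dist = xmax_distribution(params, i0, q_max)
    K = percentile(dist, q_max)
    ladder = dist.ladder.extended(K + 1)
    lpre = _log_prefix(ladder, K + 2)
    out = np.zeros(k_max)
    for i_rho in range(i0 + 1, K + 1):
        grids = _moment_log_grids(ladder, i_rho, k_max, kind="divisions")
        weight = 1.0 - np.exp(lpre[i_rho - 1] - lpre[i_rho])
        for k in range(1, k_max + 1):
            out[k - 1] += np.exp(grids[k][i0]) * weight
    return out


def conditional_division_stats(params: ModelParams, i0: int, i_rho: int,
                               ladder: Optional[RateLadder] = None) -> tuple[float, float]:
    """Mean and sd of ``N_{i0,i_rho}`` given that ``i_rho`` is reached.

    From the first two conditional factorial moments:
    ``Var = m~2/v + m - m^2`` with ``m = m~1/v``.  One extra cell needs
    exactly one division, so ``i_rho = i0 + 1`` gives (1, 0); ``i_rho ==
    i0`` needs none and gives (0, 0).
    """
    if i_rho == i0:
        return 0.0, 0.0
    if not i0 < i_rho:
        raise ValueError("conditional division stats need i0 <= i_rho")
    mom = division_factorial_moments(params, i0, i_rho, 2, ladder=ladder)
    v = mom.reach(i0)
    if v == 0.0:
        raise ZeroDivisionError("reach probability is zero; conditioning undefined")
    m = mom.moment(1, i0) / v
    var = mom.moment(2, i0) / v + m - m**2
    return m, float(np.sqrt(max(var, 0.0)))
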