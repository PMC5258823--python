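"""Expansion to a target clonal size, and the maximum clonal size.

Starting from ``i`` cells, the time ``T_{i,i_rho}`` to first reach a larger
size ``i_rho`` is *defective*: with probability ``1 - v_{i,i_rho}`` the
clonotype goes extinct first and the time is infinite.  This module
computes

* the reach probabilities ``v_{i,i_rho} = P(T_{i,i_rho} < inf)`` via the
  gambler's-ruin closed form with the zeta ladder,
* the restricted Laplace--Stieltjes transform
  ``phi_{i,i_rho}(s) = E[exp(-s T) ; T < inf]`` in product form via the
  tridiagonal forward-elimination ``g``-recursion,
* restricted moments ``m^(k) = E[T^k ; T < inf]`` by an order-ascending
  recursion, and
* the distribution of the maximum clonal size ``X_i^max`` (whose survival
  function is exactly ``v``), its percentiles ``K_q``, and the
  percentile-truncated moments of the time ``T_i^max`` to reach the
  maximum.

All zeta sums are carried in log space (log-sum-exp); restricted moments
in growth-favoured regimes reach ~1e41 while zeta terms span 1e+-500, so
linear intermediates are never formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .rates import ModelParams, RateLadder, build_ladder

__all__ = [
    "XmaxDistribution",
    "RestrictedMoments",
    "reach_probability",
    "lst_expansion",
    "expansion_moments",
    "xmax_distribution",
    "percentile",
    "xmax_mean",
    "tmax_moments",
    "conditional_passage_stats",
]


# ---------------------------------------------------------------------------
# log-space ladder sums

def _log_prefix(ladder: RateLadder, upto: int) -> np.ndarray:
    """lpre[t] = log sum_{m=0}^{t} zeta_m for t = 0..upto-1."""
    return np.logaddexp.accumulate(ladder.log_zeta[:upto])


def _log_suffix(log_zeta: np.ndarray) -> np.ndarray:
    """lsuf[t] = log sum_{j=t}^{end} zeta_j."""
    return np.logaddexp.accumulate(log_zeta[::-1])[::-1]


def _log_v(lpre: np.ndarray, i: int, i_rho: int) -> float:
    """log v_{i,i_rho} from prefix sums; v = pre[i-1]/pre[i_rho-1]."""
    if i <= 0:
        return -np.inf
    if i >= i_rho:
        return 0.0
    return float(lpre[i - 1] - lpre[i_rho - 1])


def reach_probability(params: ModelParams, i: int, i_rho: int,
                      ladder: Optional[RateLadder] = None) -> float:
    """P(reach size ``i_rho`` before extinction | start at ``i``).

    Closed form ``v_{i,i_rho} = sum_{k<i} zeta_k / sum_{m<i_rho} zeta_m``,
    evaluated in log space.  Requires ``0 <= i <= i_rho``; for shrinking
    targets the event is certain and the *time* is handled by the
    contraction module.
    """
    if not 0 <= i <= i_rho:
        raise ValueError("reach_probability requires 0 <= i <= i_rho; "
                         "for i > i_rho use contraction_moments")
    if i == 0:
        return 0.0
    if i == i_rho:
        return 1.0
    if ladder is None or ladder.i_max < i_rho - 1:
        ladder = build_ladder(params, max(i_rho - 1, 1))
    return float(np.exp(_log_v(_log_prefix(ladder, i_rho), i, i_rho)))


def lst_expansion(params: ModelParams, i: int, i_rho: int, s: float,
                  ladder: Optional[RateLadder] = None) -> float:
    """Restricted LST ``phi_{i,i_rho}(s) = E[e^{-sT}; T < inf]``.

    Product form ``prod_{k=i}^{i_rho-1} lambda_k / (s + g_k(s) + lambda_k)``
    with ``g_1(s) = mu_1`` and
    ``g_k(s) = mu_k (s + g_{k-1}) / (s + lambda_{k-1} + g_{k-1})``.
    At ``s = 0`` this reduces to the reach probability.
    """
    if s < 0:
        raise ValueError("transform argument s must be >= 0")
    if not 0 <= i <= i_rho:
        raise ValueError("lst_expansion requires 0 <= i <= i_rho")
    if i == 0:
        return 0.0
    if i == i_rho:
        return 1.0
    if ladder is None or ladder.i_max < i_rho:
        ladder = build_ladder(params, i_rho)
    lam, mu = ladder.birth, ladder.death
    log_phi = 0.0
    g = mu[1]
    for k in range(1, i_rho):
        if k >= i:
            log_phi += np.log(lam[k]) - np.log(s + g + lam[k])
        if k + 1 < i_rho:
            g = mu[k + 1] * (s + g) / (s + lam[k] + g)
    return float(np.exp(log_phi))


# ---------------------------------------------------------------------------
# restricted moments

@dataclass(frozen=True)
class RestrictedMoments:
    """Restricted moments ``m^(k)_{i,i_rho} = E[T^k; T < inf]`` on a grid.

    ``log_m[k]`` is an array over start sizes ``0..i_rho`` holding
    ``log m^(k)``; order 0 is ``log v``.  Values are exposed linearly via
    :meth:`moment` (they stay within float range in every printed regime
    even when the zeta intermediates do not).
    """

    i_rho: int
    k_max: int
    log_m: tuple  # tuple of arrays, index k = 0..k_max

    def moment(self, k: int, i: int) -> float:
        return float(np.exp(self.log_m[k][i]))

    def reach(self, i: int) -> float:
        return float(np.exp(self.log_m[0][i]))


def _moment_log_grids(ladder: RateLadder, i_rho: int, k_max: int,
                      kind: str = "time") -> list[np.ndarray]:
    """Log-space grids of restricted moments, orders 0..k_max.

    ``kind="time"`` solves the passage-time recursion (source term
    ``k m^(k-1)_n``); ``kind="divisions"`` solves the factorial-moment
    recursion of the division count (source ``lambda_n k m~^(k-1)_{n+1}``).
    Both reduce, after eliminating the tridiagonal system, to

        m^(k)_i = [ sum_n q_n * A_{max(i,n)} * B_{min(i,n)} ] / B_{i_rho}

    with prefix/suffix zeta sums ``B_t = sum_{m<t} zeta_m``,
    ``A_t = sum_{j>=t} zeta_j`` and a source vector ``q``; everything is
    accumulated with log-sum-exp.
    """
    lz = ladder.log_zeta[:i_rho]          # zeta_0 .. zeta_{i_rho-1}
    lpre = np.logaddexp.accumulate(lz)    # B_{t+1} in log
    lsuf = _log_suffix(lz)                # A_t in log
    log_denom = lpre[i_rho - 1]

    log_v = np.full(i_rho + 1, -np.inf)
    log_v[1:i_rho] = lpre[: i_rho - 1] - log_denom
    log_v[i_rho] = 0.0

    grids = [log_v]
    n_idx = np.arange(1, i_rho)
    i_idx = np.arange(1, i_rho)
    if len(n_idx):
        max_idx = np.maximum.outer(i_idx, n_idx)
        min_idx = np.minimum.outer(i_idx, n_idx)
        geom = lsuf[max_idx] + lpre[min_idx - 1]
    with np.errstate(divide="ignore"):
        log_lam = np.log(ladder.birth[: i_rho + 1])
    for k in range(1, k_max + 1):
        prev = grids[k - 1]
        log_mk = np.full(i_rho + 1, -np.inf)
        if len(n_idx):
            if kind == "time":
                log_q = np.log(k) + prev[n_idx] - log_lam[n_idx] - lz[n_idx]
            elif kind == "divisions":
                up = prev[n_idx + 1]  # includes n+1 = i_rho (log v = 0 at k=1)
                log_q = np.log(k) + up - lz[n_idx]
            else:  # pragma: no cover
                raise ValueError(kind)
            log_mk[1:i_rho] = logsumexp(log_q[None, :] + geom, axis=1) - log_denom
        grids.append(log_mk)
    return grids


def expansion_moments(params: ModelParams, i: int, i_rho: int, k_max: int,
                      ladder: Optional[RateLadder] = None) -> RestrictedMoments:
    """Restricted moments of the expansion time on the full start-size grid.

    ``i`` is the focal start size (validated to lie in ``0..i_rho``); the
    returned object holds ``m^(k)_{j,i_rho}`` for every ``j`` because the
    order-k recursion consumes order-(k-1) values at all states anyway.
    """
    if i_rho < 1 or k_max < 1:
        raise ValueError("need i_rho >= 1 and k_max >= 1")
    if not 0 <= i <= i_rho:
        raise ValueError("start size must satisfy 0 <= i <= i_rho")
    if ladder is None or ladder.i_max < i_rho:
        ladder = build_ladder(params, i_rho)
    grids = _moment_log_grids(ladder, i_rho, k_max, kind="time")
    return RestrictedMoments(i_rho=i_rho, k_max=k_max, log_m=tuple(grids))


def conditional_passage_stats(params: ModelParams, i0: int, i_rho: int,
                              ladder: Optional[RateLadder] = None) -> tuple[float, float]:
    """Mean and sd of ``T_{i0,i_rho}`` conditioned on the size being reached.

    mean = m^(1)/v, sd = sqrt(m^(2)/v - mean^2).  For ``i0 = 1``,
    ``i_rho = 2`` the conditional law is exponential with rate
    ``lambda_1 + mu_1`` and mean == sd.
    """
    if not i0 < i_rho:
        raise ValueError("conditional passage stats need i0 < i_rho")
    mom = expansion_moments(params, i0, i_rho, 2, ladder=ladder)
    v = mom.reach(i0)
    if v == 0.0:
        raise ZeroDivisionError("reach probability is zero; conditioning undefined")
    mean = mom.moment(1, i0) / v
    var = mom.moment(2, i0) / v - mean**2
    return mean, float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# maximum clonal size

@dataclass(frozen=True)
class XmaxDistribution:
    """Truncated distribution of the maximum clonal size ``X_i^max``.

    The survival function is ``P(X^max >= i_rho) = v_{i0,i_rho}`` for
    ``i_rho > i0`` (and 1 below); the pmf is the difference of consecutive
    ``v``.  ``support`` runs from ``i0`` to the smallest ``K`` whose
    cumulative mass reaches ``q_max``; ``covered_mass = 1 - v_{i0,K+1}``.
    """

    i0: int
    q_max: float
    support: np.ndarray
    pmf: np.ndarray
    cumulative: np.ndarray      # P(X^max <= x) for x in support (untruncated v)
    covered_mass: float
    ladder: RateLadder = field(repr=False)

    def survival(self, i_rho: int) -> float:
        """P(X^max >= i_rho), exact (untruncated)."""
        if i_rho <= self.i0:
            return 1.0
        return reach_probability(self.ladder.params, self.i0, i_rho, ladder=self.ladder)


def xmax_distribution(params: ModelParams, i0: int, q_max: float = 0.99,
                      max_target: int = 200_000) -> XmaxDistribution:
    """Distribution of ``X_i0^max`` truncated at cumulative mass ``q_max``."""
    if i0 < 1:
        raise ValueError("initial size must be >= 1")
    if not 0.0 < q_max < 1.0:
        raise ValueError("q_max must lie in (0, 1)")
    cap = max(4 * i0 + 16, 64)
    ladder = build_ladder(params, cap)
    while True:
        lpre = _log_prefix(ladder, ladder.i_max + 1)
        # cumulative[x] = P(X^max <= x) = 1 - v_{i0, x+1}
        xs = np.arange(i0, ladder.i_max)
        cum = 1.0 - np.exp(lpre[i0 - 1] - lpre[xs])
        hit = np.nonzero(cum > q_max)[0]
        if len(hit):
            K = int(xs[hit[0]])
            break
        if ladder.i_max >= max_target:
            raise RuntimeError(
                f"q_max={q_max} not covered below the state cap {max_target}")
        ladder = ladder.extended(min(2 * ladder.i_max, max_target))
    support = np.arange(i0, K + 1)
    surv = np.empty(len(support) + 1)
    surv[0] = 1.0
    surv[1:] = np.exp(lpre[i0 - 1] - lpre[support])  # v_{i0, x+1} for x in support
    pmf = surv[:-1] - surv[1:]
    return XmaxDistribution(
        i0=i0, q_max=q_max, support=support, pmf=pmf,
        cumulative=1.0 - surv[1:], covered_mass=float(1.0 - surv[-1]),
        ladder=ladder,
    )


def percentile(dist: XmaxDistribution, q: float) -> int:
    """Percentile ``K_q``: first ``x >= i0`` with ``P(X^max <= x) >= q``.

    An exact tie (cumulative mass equal to ``q``, e.g. mass 1/2 at the
    start size when ``lambda_1 == mu_1``) resolves to the next larger
    size, matching the convention of the published descriptor tables.
    """
    if q > dist.covered_mass:
        raise ValueError(
            f"q={q} exceeds the covered mass {dist.covered_mass:.6f}; "
            "rebuild the distribution with a larger q_max")
    idx = int(np.nonzero(dist.cumulative > q)[0][0])
    return int(dist.support[idx])


def xmax_mean(dist: XmaxDistribution) -> float:
    """Truncated expectation ``sum_{i_rho=i0}^{K_qmax} i_rho * pmf``."""
    return float(np.dot(dist.support, dist.pmf))


def tmax_moments(params: ModelParams, i0: int, k_max: int = 1,
                 q_max: float = 0.99) -> np.ndarray:
    """Truncated moments of the time ``T_i0^max`` to the maximum size.

    The exact series ``sum_{i_rho>i0} m^(k)_{i0,i_rho} (1 - v_{i_rho+1}/v_{i_rho})``
    is truncated at the (100 q_max)-th percentile of ``X^max``; the dropped
    tail carries at most ``1 - q_max`` of the conditioning mass.  Returns
    the orders ``1..k_max``.
    """
    dist = xmax_distribution(params, i0, q_max)
    K = percentile(dist, q_max)
    ladder = dist.ladder.extended(K + 1)
    lpre = _log_prefix(ladder, K + 2)
    out = np.zeros(k_max)
    for i_rho in range(i0 + 1, K + 1):
        grids = _moment_log_grids(ladder, i_rho, k_max, kind="time")
        weight = 1.0 - np.exp(lpre[i_rho - 1] - lpre[i_rho])  # 1 - v_{+1}/v
        for k in range(1, k_max + 1):
            out[k - 1] += np.exp(grids[k][i0]) * weight
    return out
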