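"""Time to accumulate a given number of division events.

``T_{i0}^D`` is the time for the clonotype, started at ``i0`` cells, to
register ``D`` proliferation (birth) events.  It is analysed through the
augmented chain ``(X(t), D(t))`` whose transient layers ``d = 0..D-1``
hold sizes ``1..i0+d``; the layer-``D`` states and the extinct states
``(0, d)`` are absorbing (target reached / target missed).  The restricted
LST satisfies, on transient states,

    Phi_(i,d)(s) = mu_i/(s+lam_i+mu_i) Phi_(i-1,d)(s)
                 + lam_i/(s+lam_i+mu_i) Phi_(i+1,d+1)(s),

which resolves by pure forward substitution: sweep layers from ``D-1``
down to ``0`` and, within a layer, sizes upward from ``Phi_(0,d) = 0``
(the same-layer neighbour is below, the cross-layer neighbour is already
known).  Restricted moments follow the differentiated system in the same
order, orders ascending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .rates import ModelParams, build_ladder

__all__ = [
    "AugmentedGrid",
    "division_time_reach_prob",
    "division_time_lst",
    "division_time_moments",
]


@dataclass(frozen=True)
class AugmentedGrid:
    """Per-layer values on the transient states of the augmented chain.

    ``layers[d]`` is an array over sizes ``0..i0+d`` (index 0 is the
    absorbed/extinct boundary, always 0).  ``value_at_start`` is the entry
    at ``(i0, 0)``, i.e. the descriptor of the physical process.
    """

    i0: int
    D: int
    layers: tuple
    log_scale: bool = False

    @property
    def value_at_start(self) -> float:
        return float(self.layers[0][self.i0])


def _sweep(params: ModelParams, i0: int, D: int, upper: float | np.ndarray,
           source=None, log: bool = False) -> AugmentedGrid:
    """Forward-substitution solve of the layered tridiagonal system.

    Solves ``f_(i,d) = a_i f_(i-1,d) + b_i g_(i+1,d+1) (+ extra_(i,d))``
    with ``a_i = mu_i/(s+lam_i+mu_i)`` style coefficients supplied via
    closures; ``upper`` is the value on the layer-D absorbing boundary.
    ``source(i, d)`` adds a per-state inhomogeneity (used by the moment
    recursion).  ``log=True`` runs the same sweep in log space (all terms
    are nonnegative), for probabilities far below float underflow.
    """
    ladder = build_ladder(params, i0 + D + 1)
    lam, mu = ladder.birth, ladder.death
    nxt: Optional[np.ndarray] = None
    layers: list[np.ndarray] = []
    for d in range(D - 1, -1, -1):
        n_states = i0 + d
        cur = np.full(n_states + 2, -np.inf) if log else np.zeros(n_states + 2)
        for i in range(1, n_states + 1):
            up = upper if d == D - 1 else nxt[i + 1]
            tot = lam[i] + mu[i]
            if log:
                term_down = np.log(mu[i] / tot) + cur[i - 1]
                term_up = np.log(lam[i] / tot) + up
                val = np.logaddexp(term_down, term_up)
                if source is not None:
                    val = np.logaddexp(val, source(i, d))
            else:
                val = (mu[i] * cur[i - 1] + lam[i] * up) / tot
                if source is not None:
                    val += source(i, d)
            cur[i] = val
        nxt = cur
        layers.append(cur[: n_states + 1])
    layers.reverse()
    return AugmentedGrid(i0=i0, D=D, layers=tuple(layers), log_scale=log)


def division_time_lst(params: ModelParams, i0: int, D: int, s: float) -> AugmentedGrid:
    """Restricted LST ``Phi^D_(i,d)(s)`` on the full transient grid.

    ``s = 0`` yields the reach probabilities ``w``; ``D = 0`` is the empty
    target (grid with value 1 at the start by convention).
    """
    if s < 0:
        raise ValueError("transform argument s must be >= 0")
    if i0 < 1 or D < 0:
        raise ValueError("need i0 >= 1 and D >= 0")
    if D == 0:
        return AugmentedGrid(i0=i0, D=0, layers=(np.array([0.0] * i0 + [1.0]),))
    ladder = build_ladder(params, i0 + D + 1)
    lam, mu = ladder.birth, ladder.death
    nxt: Optional[np.ndarray] = None
    layers: list[np.ndarray] = []
    for d in range(D - 1, -1, -1):
        n_states = i0 + d
        cur = np.zeros(n_states + 2)
        for i in range(1, n_states + 1):
            up = 1.0 if d == D - 1 else nxt[i + 1]
            cur[i] = (mu[i] * cur[i - 1] + lam[i] * up) / (s + lam[i] + mu[i])
        nxt = cur
        layers.append(cur[: n_states + 1])
    layers.reverse()
    return AugmentedGrid(i0=i0, D=D, layers=tuple(layers))


def division_time_reach_prob(params: ModelParams, i0: int, D: int,
                             log: bool = False) -> tuple[float, AugmentedGrid]:
    """``P(T_{i0}^D < inf)`` and the full grid of ``w`` values.

    With ``log=True`` the sweep runs in log space and the grid holds log
    probabilities (hostile regimes push ``w`` far below 1e-300).
    """
    if i0 < 1 or D < 0:
        raise ValueError("need i0 >= 1 and D >= 0")
    if D == 0:
        val = 0.0 if log else 1.0
        return (val if not log else 0.0), AugmentedGrid(
            i0=i0, D=0, layers=(np.array([0.0] * i0 + [1.0]),), log_scale=log)
    if log:
        grid = _sweep(params, i0, D, upper=0.0, log=True)
    else:
        grid = division_time_lst(params, i0, D, 0.0)
    return grid.value_at_start, grid


def division_time_moments(params: ModelParams, i0: int, D: int,
                          k_max: int = 2) -> tuple[np.ndarray, float, float]:
    """Restricted moments of ``T_{i0}^D`` and conditional (mean, sd).

    Solves, orders ascending,

        m^(k)_(i,d) = k/(lam_i+mu_i) m^(k-1)_(i,d)
                    + mu_i/(lam_i+mu_i) m^(k)_(i-1,d)
                    + lam_i/(lam_i+mu_i) m^(k)_(i+1,d+1)

    and returns (restricted moments at the start, orders 1..k_max;
    conditional mean m1/w; conditional sd from the first two orders).
    """
    if i0 < 1 or D < 0:
        raise ValueError("need i0 >= 1 and D >= 0")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if D == 0:
        return np.zeros(k_max), 0.0, 0.0
    w, grid_w = division_time_reach_prob(params, i0, D)
    if w == 0.0:
        raise ZeroDivisionError("reach probability is zero; conditioning undefined")
    ladder = build_ladder(params, i0 + D + 1)
    lam, mu = ladder.birth, ladder.death
    grids = [grid_w]
    restricted = np.zeros(k_max)
    for k in range(1, k_max + 1):
        prev = grids[k - 1]

        def source(i: int, d: int, _k=k, _prev=prev) -> float:
            return _k * _prev.layers[d][i] / (lam[i] + mu[i])

        grid_k = _sweep(params, i0, D, upper=0.0, source=source)
        grids.append(grid_k)
        restricted[k - 1] = grid_k.value_at_start
    mean = restricted[0] / w
    sd = 0.0
    if k_max >= 2:
        var = restricted[1] / w - mean**2
        sd = float(np.sqrt(max(var, 0.0)))
    return restricted, mean, sd
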