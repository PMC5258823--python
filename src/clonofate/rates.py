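"""Model parameters and state-dependent birth/death rates.

The clonotype of interest is a continuous-time birth--death chain on the
clonal sizes {0, 1, 2, ...}, with 0 absorbing (extinction).  A cell divides
when it receives a homeostatic proliferation signal; signals are shared with
``nu`` competing clonotypes of characteristic size ``n_mean``, which gives
the size-dependent per-clonotype birth rate

    lambda_i = phi * exp(-nu) * sum_r nu^r / r! * i / (r * n_mean + i),

while every cell dies independently at rate ``mu`` (``mu_i = mu * i``).
Two limits of the competition parameter have closed forms: the *hard* niche
(nu -> 0, no competitors, lambda_i = phi for i >= 1) and the *soft* niche
(nu -> infinity at fixed nu * n_mean, lambda_i = phi * i / (nu*n_mean + i)).

Everything downstream consumes rates through a :class:`RateLadder`, which
also tabulates the log-scale products zeta_i = prod_k mu_k / lambda_k used
by every first-passage recursion.  zeta spans hundreds of orders of
magnitude in realistic regimes, so it is only ever stored as a log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import stats

__all__ = ["ModelParams", "RateLadder", "birth_rate", "death_rate", "build_ladder"]

Regime = Literal["exact", "hard", "soft"]

#: Poisson tail mass discarded on each side when the exact-regime series is
#: truncated to a central window of r values.
_POISSON_TAIL = 1e-13


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the clonotype birth--death model.

    Parameters
    ----------
    mu:
        Per-cell death rate (1/time).  Must be positive.  With ``mu = 1``
        the time unit is the mean lifetime of a naive T cell.
    phi:
        Homeostatic signalling (proliferation) rate (1/time).  Must be
        positive.  Encodes both affinity and cross-reactivity of the TCR.
    nu:
        Mean number of competing clonotypes (dimensionless, >= 0).
    n_mean:
        Characteristic clonal size of each competitor (cells, >= 1).
    regime:
        ``"exact"`` (full Poisson series), ``"hard"`` (no competition,
        lambda_i = phi) or ``"soft"`` (large-competition limit).  When not
        given it resolves to ``"hard"`` if ``nu == 0`` and ``"exact"``
        otherwise; the soft limit is only applied on explicit request.
    """

    mu: float
    phi: float
    nu: float = 0.0
    n_mean: float = 1.0
    regime: Optional[Regime] = None
    _resolved: Regime = field(init=False, repr=False, compare=False, default="exact")

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not self.phi > 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if self.nu < 0:
            raise ValueError(f"nu must be nonnegative, got {self.nu}")
        if self.n_mean < 1:
            raise ValueError(f"n_mean must be >= 1 cell, got {self.n_mean}")
        regime = self.regime
        if regime is None:
            regime = "hard" if self.nu == 0 else "exact"
        elif regime not in ("exact", "hard", "soft"):
            raise ValueError(f"unknown regime {regime!r}")
        object.__setattr__(self, "_resolved", regime)

    @property
    def resolved_regime(self) -> Regime:
        """The niche regime actually used for rate evaluation."""
        return self._resolved


@dataclass(frozen=True)
class RateLadder:
    """Tabulated rates and log-scale zeta ladder up to a working cap.

    ``log_zeta[i]`` is ``log prod_{k=1..i} mu_k / lambda_k`` with
    ``log_zeta[0] == 0`` (empty product).  ``birth[0] == death[0] == 0``
    because extinction is absorbing.
    """

    params: ModelParams
    i_max: int
    birth: np.ndarray
    death: np.ndarray
    log_zeta: np.ndarray

    def extended(self, new_i_max: int) -> "RateLadder":
        """Return a ladder with a cap of at least ``new_i_max``."""
        if new_i_max <= self.i_max:
            return self
        return build_ladder(self.params, new_i_max)


def _poisson_window(nu: float) -> tuple[np.ndarray, np.ndarray]:
    """Central window of Poisson(nu) support holding >= 1 - 2e-13 mass."""
    if nu == 0.0:
        return np.array([0]), np.array([1.0])
    lo = int(stats.poisson.ppf(_POISSON_TAIL, nu))
    hi = int(stats.poisson.ppf(1.0 - _POISSON_TAIL, nu)) + 1
    r = np.arange(max(lo, 0), hi + 1)
    # pmf computed stably from log to survive nu ~ hundreds
    w = np.exp(stats.poisson.logpmf(r, nu))
    return r, w


def birth_rates(params: ModelParams, i: np.ndarray) -> np.ndarray:
    """Vectorised birth rate lambda_i; lambda_0 = 0 in all regimes."""
    i = np.asarray(i)
    if np.any(i < 0):
        raise ValueError("clonal size must be nonnegative")
    i = i.astype(float)
    regime = params.resolved_regime
    if regime == "hard":
        lam = np.where(i > 0, params.phi, 0.0)
    elif regime == "soft":
        denom = params.nu * params.n_mean + i
        with np.errstate(invalid="ignore"):
            lam = np.where(i > 0, params.phi * i / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        r, w = _poisson_window(params.nu)
        denom = r * params.n_mean + i[..., None]
        frac = i[..., None] / np.where(denom > 0, denom, 1.0)  # r=0, i=0 term is 0
        lam = params.phi * (w * frac).sum(axis=-1)
    return lam


def birth_rate(params: ModelParams, i: int) -> float:
    """Birth rate lambda_i of a clonotype of size ``i`` (1/time)."""
    if i < 0:
        raise ValueError("clonal size must be nonnegative")
    return float(birth_rates(params, np.array([i]))[0])


def death_rate(params: ModelParams, i: int) -> float:
    """Death rate mu_i = mu * i (1/time); linear in the clonal size."""
    if i < 0:
        raise ValueError("clonal size must be nonnegative")
    return params.mu * i


def build_ladder(params: ModelParams, i_max: int) -> RateLadder:
    """Tabulate rates and the log-zeta ladder for sizes 0..i_max."""
    if i_max < 1:
        raise ValueError("i_max must be >= 1")
    sizes = np.arange(i_max + 1)
    birth = birth_rates(params, sizes)
    death = params.mu * sizes.astype(float)
    log_zeta = np.zeros(i_max + 1)
    log_zeta[1:] = np.cumsum(np.log(death[1:]) - np.log(birth[1:]))
    return RateLadder(params=params, i_max=i_max, birth=birth, death=death, log_zeta=log_zeta)
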