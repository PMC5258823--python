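"""Exact stochastic simulation of the clonotype birth--death chain.

Serves as the independent Monte-Carlo oracle for every analytic
descriptor.  Waiting times are exponential with total rate
``lambda_i + mu_i`` and the embedded chain moves up with probability
``lambda_i / (lambda_i + mu_i)`` -- the Gillespie algorithm for a
univariate chain.  Each trajectory records its running maximum (size,
first time at it, births up to it) and optional first-passage /
division-count marks.

Replicates are simulated in fixed-size blocks; each block draws from its
own child stream of the root seed, and trajectories within a block are
advanced in lockstep with numpy, so estimates are bit-reproducible for a
given (seed, params, caps) and earlier blocks are unchanged when the
replicate count grows by whole blocks.

Growth-favoured regimes have astronomically long extinction times; caps
on events and time are enforced and capped paths are reported as censored
rather than silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .rates import ModelParams, birth_rates

__all__ = [
    "Trajectory",
    "MonteCarloEstimate",
    "simulate_trajectory",
    "simulate_block",
    "estimate_descriptors",
]

BLOCK_SIZE = 8192


@dataclass(frozen=True)
class Trajectory:
    """One simulated path, with event log and recorded summaries."""

    i0: int
    times: np.ndarray        # event times
    sizes: np.ndarray        # size after each event
    is_birth: np.ndarray     # event types
    xmax: int                # maximum size attained
    t_max: float             # first time the running maximum is attained
    n_max: int               # births in [0, t_max]
    censored: bool
    extinction_time: float   # nan when censored
    first_passage: dict = field(default_factory=dict)   # size -> (time, births) or None
    division_time: dict = field(default_factory=dict)   # D -> time or None


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Point estimate with its Monte-Carlo standard error.

    ``censored_fraction`` is always reported; estimates over paths that
    hit a cap are flagged unreliable instead of being dropped silently.
    """

    value: float
    std_error: float
    n: int
    censored_fraction: float
    reliable: bool = True


class _LamTable:
    """Birth-rate lookup extended on demand (doubling)."""

    def __init__(self, params: ModelParams, cap: int = 256):
        self.params = params
        self.table = birth_rates(params, np.arange(cap + 1))

    def __call__(self, sizes: np.ndarray) -> np.ndarray:
        top = int(sizes.max(initial=0))
        while top >= len(self.table):
            self.table = birth_rates(
                self.params, np.arange(2 * len(self.table)))
        return self.table[sizes]


def simulate_trajectory(params: ModelParams, i0: int, rng: np.random.Generator,
                        max_events: int = 1_000_000, max_time: float = np.inf,
                        passage_targets: tuple = (), division_targets: tuple = ()) -> Trajectory:
    """Simulate one path from size ``i0`` until extinction or a cap.

    Pre-draws uniforms in chunks; two per event (waiting time, event
    type).  ``passage_targets`` are sizes whose first-hit time and
    division count are marked; ``division_targets`` are cumulative birth
    counts whose first-hit times are marked.
    """
    if i0 < 1:
        raise ValueError("initial size must be >= 1")
    lam_of = _LamTable(params, max(4 * i0, 64))
    times, sizes, kinds = [], [], []
    t, size, births = 0.0, i0, 0
    xmax, t_max, n_max = i0, 0.0, 0
    fp = {s: ((0.0, 0) if s == i0 else None) for s in passage_targets}
    dt_marks = {d: (0.0 if d == 0 else None) for d in division_targets}
    censored = False
    chunk = np.empty((0, 2))
    pos = 0
    for _ in range(max_events):
        if size == 0:
            break
        if pos >= len(chunk):
            chunk = rng.random((512, 2))
            pos = 0
        u1, u2 = chunk[pos]
        pos += 1
        lam = float(lam_of(np.array([size]))[0])
        mu_i = params.mu * size
        tot = lam + mu_i
        t += -np.log(u1) / tot
        if t > max_time:
            censored = True
            break
        was_birth = u2 * tot < lam
        if was_birth:
            size += 1
            births += 1
            if births in dt_marks and dt_marks[births] is None:
                dt_marks[births] = t
        else:
            size -= 1
        times.append(t)
        sizes.append(size)
        kinds.append(was_birth)
        if size in fp and fp[size] is None:
            fp[size] = (t, births)
        if size > xmax:
            xmax, t_max, n_max = size, t, births
    else:
        censored = size > 0
    return Trajectory(
        i0=i0, times=np.array(times), sizes=np.array(sizes, dtype=int),
        is_birth=np.array(kinds, dtype=bool), xmax=xmax, t_max=t_max,
        n_max=n_max, censored=censored,
        extinction_time=(t if (not censored and size == 0) else np.nan),
        first_passage=fp, division_time=dt_marks,
    )


def simulate_block(params: ModelParams, i0: int, n: int, rng: np.random.Generator,
                   max_events: int = 1_000_000, max_time: float = np.inf,
                   up_target: Optional[int] = None,
                   div_target: Optional[int] = None,
                   down_target: Optional[int] = None,
                   until: str = "extinction") -> dict:
    """Advance ``n`` trajectories in lockstep; return per-path summaries.

    ``until="marks"`` deactivates a path as soon as all requested marks
    are resolved (reached, or extinct hence unreachable) -- essential in
    regimes whose extinction times are beyond any simulation budget.
    """
    sizes = np.full(n, i0, dtype=np.int64)
    t = np.zeros(n)
    births = np.zeros(n, dtype=np.int64)
    events = np.zeros(n, dtype=np.int64)
    xmax = np.full(n, i0, dtype=np.int64)
    t_max = np.zeros(n)
    n_max = np.zeros(n, dtype=np.int64)
    censored = np.zeros(n, dtype=bool)

    t_up = np.full(n, np.nan)
    n_up = np.full(n, -1, dtype=np.int64)
    t_div = np.full(n, np.nan)
    t_down = np.full(n, np.nan)
    if up_target is not None and i0 >= up_target:
        t_up[:] = 0.0
        n_up[:] = 0
    if div_target is not None and div_target == 0:
        t_div[:] = 0.0
    if down_target is not None and i0 <= down_target:
        t_down[:] = 0.0

    lam_of = _LamTable(params, max(4 * i0, 64))
    active = sizes > 0
    while True:
        if until == "marks":
            pending = np.zeros(n, dtype=bool)
            if up_target is not None:
                pending |= np.isnan(t_up)
            if div_target is not None:
                pending |= np.isnan(t_div)
            if down_target is not None:
                pending |= np.isnan(t_down)
            run = active & pending
        else:
            run = active
        idx = np.nonzero(run)[0]
        if not len(idx):
            break
        s = sizes[idx]
        lam = lam_of(s)
        mu_i = params.mu * s
        tot = lam + mu_i
        u = rng.random((2, len(idx)))
        t[idx] += -np.log(u[0]) / tot
        birth = u[1] * tot < lam
        sizes[idx] = s + np.where(birth, 1, -1)
        births[idx] += birth
        events[idx] += 1

        s_new = sizes[idx]
        t_new = t[idx]
        # running maximum: each strict record is set by a birth
        rec = s_new > xmax[idx]
        upd = idx[rec]
        xmax[upd] = s_new[rec]
        t_max[upd] = t_new[rec]
        n_max[upd] = births[upd]
        if up_target is not None:
            hit = (s_new == up_target) & np.isnan(t_up[idx])
            t_up[idx[hit]] = t_new[hit]
            n_up[idx[hit]] = births[idx[hit]]
        if div_target is not None:
            hit = (births[idx] >= div_target) & np.isnan(t_div[idx]) & birth
            t_div[idx[hit]] = t_new[hit]
        if down_target is not None:
            hit = (s_new == down_target) & np.isnan(t_down[idx])
            t_down[idx[hit]] = t_new[hit]

        capped = (events[idx] >= max_events) | (t[idx] >= max_time)
        censored[idx[capped & (s_new > 0)]] = True
        active[idx] = (s_new > 0) & ~capped
    ext_time = np.where(~censored & (sizes == 0), t, np.nan)
    return {
        "xmax": xmax, "t_max": t_max, "n_max": n_max,
        "births": births, "extinction_time": ext_time, "censored": censored,
        "t_up": t_up, "n_up": n_up, "t_div": t_div, "t_down": t_down,
    }


def _estimate(values: np.ndarray, valid: np.ndarray, censored: np.ndarray,
              threshold: float) -> MonteCarloEstimate:
    frac = float(censored.mean()) if len(censored) else 0.0
    vals = values[valid]
    n = len(vals)
    if n == 0:
        return MonteCarloEstimate(np.nan, np.nan, 0, frac, reliable=False)
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.inf
    return MonteCarloEstimate(float(vals.mean()), se, n, frac,
                              reliable=frac <= threshold)


def estimate_descriptors(params: ModelParams, i0: int, n_reps: int, seed: int,
                         max_events: int = 1_000_000, max_time: float = np.inf,
                         up_target: Optional[int] = None,
                         div_target: Optional[int] = None,
                         down_target: Optional[int] = None,
                         until: str = "extinction",
                         censored_threshold: float = 0.01,
                         block_size: int = BLOCK_SIZE) -> dict[str, MonteCarloEstimate]:
    """Monte-Carlo estimates of the stochastic descriptors.

    Always estimates E[X^max], E[T^max], E[N^max] and the extinction time
    (over uncensored paths, with the censored fraction attached); when
    targets are given, also the reach probability and conditional moments
    of the first-passage time/division count to ``up_target``, the time
    to ``div_target`` divisions, and the contraction time to
    ``down_target``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = np.random.SeedSequence(seed)
    blocks = []
    remaining = n_reps
    for child in root.spawn((n_reps + block_size - 1) // block_size):
        n = min(block_size, remaining)
        remaining -= n
        blocks.append(simulate_block(
            params, i0, n, np.random.default_rng(child),
            max_events=max_events, max_time=max_time, up_target=up_target,
            div_target=div_target, down_target=down_target, until=until))
    agg = {k: np.concatenate([b[k] for b in blocks]) for k in blocks[0]}
    cens = agg["censored"]
    ok = ~cens
    out: dict[str, MonteCarloEstimate] = {}
    if until != "marks":
        out["xmax_mean"] = _estimate(agg["xmax"].astype(float), ok, cens, censored_threshold)
        out["tmax_mean"] = _estimate(agg["t_max"], ok, cens, censored_threshold)
        out["nmax_mean"] = _estimate(agg["n_max"].astype(float), ok, cens, censored_threshold)
        out["extinction_time_mean"] = _estimate(
            agg["extinction_time"], ok, cens, censored_threshold)
    if up_target is not None:
        reached = ~np.isnan(agg["t_up"])
        resolved = reached | ok  # extinct-before-target paths resolve to "not reached"
        out["reach_prob"] = _estimate(
            reached.astype(float), resolved, cens, censored_threshold)
        out["passage_time_given_reach"] = _estimate(
            agg["t_up"], reached, cens, censored_threshold)
        out["divisions_given_reach"] = _estimate(
            agg["n_up"].astype(float), reached, cens, censored_threshold)
    if div_target is not None:
        reached = ~np.isnan(agg["t_div"])
        resolved = reached | ok
        out["division_reach_prob"] = _estimate(
            reached.astype(float), resolved, cens, censored_threshold)
        out["division_time_given_reach"] = _estimate(
            agg["t_div"], reached, cens, censored_threshold)
    if down_target is not None:
        hit = ~np.isnan(agg["t_down"])
        out["contraction_time_mean"] = _estimate(
            agg["t_down"], hit, cens, censored_threshold)
        sd_est = out["contraction_time_mean"]
        vals = agg["t_down"][hit]
        if len(vals) > 1:
            out["contraction_time_sd"] = MonteCarloEstimate(
                float(vals.std(ddof=1)),
                float(vals.std(ddof=1) / np.sqrt(2 * (len(vals) - 1))),
                len(vals), sd_est.censored_fraction, sd_est.reliable)
    return out
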