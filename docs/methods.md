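# Methods

## Model

The clonotype of interest is a univariate birth–death chain `X(t)` on the
nonnegative integers, the reduction of a multi-clonotype competition
process in which all competitors are summarised by their number `ν` and
characteristic size `⟨n⟩`. Per-clonotype birth (division) and death
rates are

    λ_i = φ e^{-ν} Σ_{r≥0} (ν^r/r!) · i/(r⟨n⟩ + i),      μ_i = μ i,

with `λ_0 = 0` in every regime: state 0 (extinction) is absorbing, and
reading the hard-niche display `λ_i = φ` literally at `i = 0` would
contradict that, so the constant hard-niche rate applies for `i ≥ 1`
only. Extinction is certain for all parameter values, which is why the
descriptors below target the transient excursion rather than a
stationary law.

Parameters, units and defaults:

| parameter | meaning | units | constraint |
|---|---|---|---|
| `mu` | per-cell death rate | 1/time | > 0; `mu = 1` makes the time unit one mean T cell lifetime |
| `phi` | homeostatic signalling rate | 1/time | > 0 |
| `nu` | mean number of competitor clonotypes | – | ≥ 0, default 0 |
| `n_mean` | characteristic competitor size | cells | ≥ 1, default 1 |
| `regime` | `exact` / `hard` / `soft` | – | auto: `hard` iff `nu == 0`, else `exact`; `soft` only on request |

The Poisson series in the exact regime is truncated to the central
window of `r` values carrying all but `1e-13` of the Poisson(`ν`) mass
on each side, with masses evaluated from `logpmf`; this keeps the rate
accurate to ~1e-12 relative even at `ν = 200`, where naive term-by-term
summation in linear space would overflow the factorials.

## Numerical backbone: the log-space zeta ladder

Every first-passage quantity is built from `ζ_0 = 1`,
`ζ_i = Π_{k=1..i} μ_k/λ_k`. In realistic regimes (`φ = 100`, hard
niche) `ζ` sweeps through 1e±500, so the ladder is only ever stored as
`log ζ`, and all sums of ζ-terms use `logaddexp` accumulation /
log-sum-exp. Prefix sums `B_t = Σ_{m<t} ζ_m` and suffix sums
`A_t = Σ_{j≥t} ζ_j` are the only aggregates needed:

* reach probabilities: `v_{i,i_ρ} = B_i / B_{i_ρ}`;
* restricted moments of the expansion time: the tridiagonal first-step
  system, after elimination, collapses to
  `m^(k)_i = [Σ_n q_n A_{max(i,n)} B_{min(i,n)}] / B_{i_ρ}`
  with source `q_n = k m^(k-1)_n / (λ_n ζ_n)`, evaluated order by
  order. Factorial moments of the division count use the same kernel
  with source `k m̃^(k-1)_{n+1} / ζ_n`. All terms are nonnegative, so
  log-sum-exp is exact up to rounding and no cancellation occurs.

Restricted moments themselves are held linearly (they stay below ~1e43
in every tabulated regime, far inside double range) but logs are taken
when they enter the next order's source.

## Maximum clonal size, its time, and its division count

`P(X_i^max ≥ i_ρ) = v_{i,i_ρ}` for `i_ρ > i` gives the pmf by
differencing. The percentile `K_q` is the first size whose cumulative
mass reaches `q`; an exact tie (e.g. cumulative exactly 1/2 at the start
size when `λ_1 = μ_1`) resolves to the next larger size — the
convention that reproduces the published descriptor tables, whose
`φ = 1` row has two such ties. The series for the moments of `T_i^max`
and the factorial moments of `N_i^max`,

    Σ_{i_ρ>i} m^(k)_{i,i_ρ} (1 − v_{i,i_ρ+1}/v_{i,i_ρ}),

are truncated at `K_{q_max}` (default `q_max = 0.99`, overridable, e.g.
0.999 where `K_0.99 = 1` would be uninformative), so the neglected
conditioning mass is at most `1 − q_max`. The truncated mean of
`X^max` includes the `i_ρ = i0` term. Truncated tail probabilities are
reported as `P̃(X^max ≥ K_q) = v_{K_q} − v_{K_{q_max}+1}`, i.e. the
mass actually covered by the truncation. Standard deviations of the
defective passage variables are always reported conditionally on the
reach event; note that the conditional division count to `i0 + 1` is
deterministic (= 1) only from `i0 = 1`, since larger starts can dip
below `i0` and divide again on the way.

## Contraction and extinction times

For `i_ρ < i` absorption is certain and the Karlin–McGregor series

    E[T^k_{i,i_ρ}] = k Σ_{n=i_ρ}^{i-1} ρ_n Σ_{j>n} E[T^{k-1}_{j,i_ρ}]/(λ_j ρ_j)

applies, with `ρ_n = ζ_n/ζ_{i_ρ}`. The inner series converges
factorially (`λ_j ≤ φ`, `μ_j = μ j`), and is truncated when the next
term falls below `tail_tol` (default 1e-12) times the running sum; the
order-`k` grid is computed for all starts up to the adaptive cap so
order `k−1` is never recomputed. Halving `tail_tol` moves the mean by
less than `tail_tol × E[T]`; `i_ρ = 0` (extinction) is allowed and the
strong-Markov additivity `E[T_{i,i_ρ}] = E[T_{i,m}] + E[T_{m,i_ρ}]`
serves as a free cross-check in the tests.

## Time to D division events

The augmented chain `(X(t), D(t))` has transient layers `d = 0..D−1`
holding sizes `1..i0+d`; reaching layer `D` is the target, `(0, d)` is
failure. The restricted LST equations couple a state to its same-layer
lower neighbour and its next-layer upper neighbour, so the whole system
resolves by pure forward substitution — layers from `D−1` down to 0,
sizes ascending from the zero boundary — with no matrix inversion; the
restricted-moment recursion is solved in the same order, orders
ascending. A log-space variant of the probability sweep is available for
hostile regimes where `P(T^D < ∞)` underflows (the tables bound some
cells below 1e-18); the default linear output documents underflow to 0.

## Gillespie simulator

The simulator draws exponential waiting times with rate `λ_i + μ_i` and
birth indicators with probability `λ_i/(λ_i + μ_i)` — exact simulation,
no tau-leaping. Replicates are organised in blocks of 8192 paths; each
block gets its own child stream spawned from the root seed and its paths
are advanced in lockstep with numpy. Estimates are therefore
bit-reproducible for a given (seed, parameters, caps), and enlarging the
replicate count by whole blocks leaves earlier blocks untouched; this
block-stream design trades the finer per-path stream granularity for an
order-of-magnitude speedup (1e5 extinction paths at `φ = 5` in a few
seconds on one core). Growth-favoured regimes have extinction times up
to ~1e41 lifetimes, far beyond any simulation budget, so event- and
time-caps censor such paths: censored fractions are always reported,
estimates with more than 1% censoring are flagged unreliable, and the
analytic routes are the only ones exercised there. Per-path trajectories
with full event logs are available separately for diagnostics.

What the simulator does and does not emulate: it samples the exact
univariate reduction of the competition model, so agreement with the
analytic descriptors validates the recursions and their truncation
rules — it cannot validate the reduction itself (competitors are never
simulated explicitly, and time-varying or age-structured rates are out
of scope).

## Problem sizes and tolerances used in the checks

The test suite and the acceptance script run the analytic descriptors at
the published parameter points (hard niche `φ ∈ {0.1, 1, 5}`, crowded
intermediate niche `(ν,⟨n⟩,φ) = (50,50,50)`, soft niche `φ = 1000`,
`ν = 200`) and Monte-Carlo comparisons at 3e4–1e5 replicates, agreeing
within three standard errors; 1e5 replicates put the standard error of
the mean maximum size at ~0.015 cells at `φ = 5`. Dense linear solves of
the small first-step systems (grid sizes ≤ 9, `D ≤ 3`) act as
independent oracles for the ladder recursions at relative tolerance
1e-10. Published five-decimal table values are matched to the printed
precision; the comparison allows one unit in the last printed decimal
because those tables evidently truncate rather than round their final
digit.

## Known limitations

* The untruncated `E[X^max]` is not computed — the residual series has
  no tractable closed form, and only truncated values are reported
  (with the Gillespie estimate as the untruncated reference where
  simulation is feasible).
* Conditional standard deviations computed from first and second
  restricted moments lose precision when sd/mean is far below 1e-8
  (catastrophic cancellation); in the tabulated regimes sd ≈ mean and
  this is immaterial.
* The pmf recursion for the division count is dense in (start, count)
  and intended for small targets; moments should come from the
  factorial-moment recursion instead.
* `AugmentedGrid` memory grows as `i0·D + D²/2`; fine for the tabulated
  grids (`i0 ≤ 100`, `D ≤ 10`), not meant for `D` in the thousands.
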