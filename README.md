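# clonofate

Stochastic descriptors for the fate and potential of naive T cell
clonotypes competing for homeostatic proliferation signals in the
periphery.

## The problem

A recent thymic emigrant (RTE) seeds the periphery as a single naive T
cell. Whether its clonotype becomes established or dies out quickly
depends on how much homeostatic stimulation its T cell receptor can
harvest while competing with the resident repertoire. `clonofate` models
the clonal size `X(t)` as a continuous-time birth–death chain on
`{0, 1, 2, ...}` with rates

```
λ_i = φ e^{-ν} Σ_{r≥0} (ν^r / r!) · i / (r⟨n⟩ + i),      μ_i = μ i,
```

where `φ` is the signalling rate (affinity × cross-reactivity of the
TCR), `ν` the mean number of competing clonotypes, `⟨n⟩` their
characteristic clonal size and `μ` the per-cell death rate. Two limits
have closed forms: the *hard niche* (`ν → 0`, `λ_i = φ`) and the *soft
niche* (`ν → ∞`, `λ_i = φ i/(ν⟨n⟩ + i)`). State 0 is absorbing and
extinction is certain; the interesting questions are about the transient
excursion before extinction:

* `X_i^max` — the maximum clonal size ever attained from `i` cells, with
  `P(X_i^max ≥ i_ρ) = v_{i,i_ρ}`, the classical ruin probability built
  from the ladder `ζ_k = Π_{j≤k} μ_j/λ_j`;
* `T_i^max`, `N_i^max` — the time and the number of division events
  needed to first reach that maximum, obtained from restricted
  Laplace–Stieltjes transforms / probability generating functions of the
  defective passage variables `T_{i,i_ρ}`, `N_{i,i_ρ}` and percentile
  truncation of the resulting series;
* `T_{i,i_ρ}` with `i_ρ < i` — the contraction time on the way to
  extinction, through the Karlin–McGregor series;
* `T_i^D` — the time to accumulate `D` division events, through an
  augmented `(size, divisions)` absorbing chain solved by forward
  substitution.

Every analytic descriptor is cross-validated by an exact Gillespie
simulator that doubles as a Monte-Carlo estimator with standard errors.
The audience is mathematical immunologists and applied probabilists
studying first-passage descriptors of absorbing birth–death processes.

## Worked example

A hard-niche clonotype (`ν = 0`) with signalling rate `φ = 5` and death
rate `μ = 1` (time measured in mean T cell lifetimes), seeded by a
single RTE:

```python
from clonofate import (ModelParams, estimate_descriptors, tmax_moments,
                       xmax_distribution, xmax_mean)

p = ModelParams(mu=1.0, phi=5.0)
dist = xmax_distribution(p, i0=1, q_max=0.99)
print(xmax_mean(dist))                  # 8.404942141295493
print(tmax_moments(p, 1)[0])            # 12.723379884445082
est = estimate_descriptors(p, 1, 100_000, seed=1)
print(est["xmax_mean"].value)           # 8.50885
```

The truncated mean maximum size is ~8.4 cells: the clonotype either dies
almost immediately (mass of `X^max` near 1) or establishes itself around
the second mode of a bimodal distribution. The simulated untruncated
mean is ~8.51, about 1% above the analytic value because the truncation
at the 99th percentile (`K_0.99 = 16`) drops only tail mass. The same
numbers come from the command line:

```
$ clonofate xmax --phi 5.0 --mu 1.0 --format json
  ... "E_Xmax": 8.4049421413, "E_Tmax": 12.7233798844,
      "E_Nmax": 67.1535762724, "K_0.99": 16 ...
```

A soft-niche clonotype facing 200 competitors of size 10, asking for the
chance of five division events from 10 initial cells:

```
$ clonofate divtime --phi 1000 --nu 200 --n-mean 10 --regime soft --mu 1 --i0 10 -D 5
mu,phi,nu,n_mean,regime,i0,D,P_reach,E_T_given_reach,sd_T_given_reach
1.0,1000.0,200.0,10.0,soft,10,5,0.7481620759789397,1.2815398771972095,0.8924830723335047
```

so the proliferative potential is reached with probability 0.748, and,
when it is, after 1.28 ± 0.89 lifetimes. Subcommands `divisions`,
`contraction`, `simulate` and `table` cover the remaining descriptors;
every flag can also come from a JSON/YAML config file.

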