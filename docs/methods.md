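# Methods

`lousepop` implements the two quantitative analyses that make up a classic
bird-louse population study: host-level **aggregation analysis** of louse
counts across a sample of examined birds, and **cohort demography** from in
vitro rearing data. A seeded synthetic-data module emulates both raw
datasets (the per-bird census and the per-individual rearing records),
which are typically never deposited.

## Aggregation analysis

### Descriptive statistics

For a vector of counts `x_1..x_N` (lice per examined host):

- prevalence = (number of hosts with `x_i > 0`) / N,
- mean intensity = mean count over infested hosts,
- sample mean abundance = mean count over all hosts,

so that `abundance = prevalence × intensity` holds as an exact identity
whenever at least one host is infested. The variance is the unbiased
(n−1) sample variance throughout; mean intensity is reported as an
explicit `None` (never 0) when no host is infested, so an uninfested
sample cannot silently masquerade as a lightly infested one.

### Negative-binomial exponent k

Aggregation is modelled by the negative binomial with mean `m` and shape
(exponent) `k`; smaller `k` means stronger aggregation, and the
variance-to-mean ratio is `1 + m/k`. Two estimators are provided:

- **moments**: `k = m² / (s² − m)`, defined only for overdispersed samples
  (`s² > m`); otherwise an error is raised.
- **maximum likelihood** (the headline estimate): the mean is fixed at the
  sample mean (its MLE under this model) and the profile log-likelihood is
  maximized over `log k` by bounded scalar search on `k ∈ [10⁻⁸, 10⁸]`
  (`xatol` default 10⁻¹⁰, iteration cap 200). When the data carry no
  aggregation signal (e.g. all counts equal) the likelihood increases
  monotonically toward the Poisson limit `k → ∞`; the optimizer then hits
  the boundary and the fit is returned with `converged=False` rather than
  a spurious finite `k`.

### Index of discrepancy D

With counts sorted ascending, `D = 1 − 2·Σᵢ cᵢ / (m·N·(N+1))` where `cᵢ`
is the cumulative sum through host `i`. D is 0 when every host carries the
same count, approaches 1 as one host monopolizes the population, is
invariant under permutation of hosts, and satisfies the Pigou–Dalton
property (moving one louse from a poorer to a strictly richer host
increases D). D equals the sample Gini coefficient times `N/(N+1)` — the
tests exploit this as an independent brute-force oracle via the
mean-absolute-difference form of Gini.

### Chi-square goodness of fit

Observed count frequencies in classes `0, 1, 2, …, max` plus a single open
tail are compared with negative-binomial expectations for the fitted
`(m, k)`. Under-populated classes are pooled *from the tail inward*
(repeatedly merging the last class with expected count below
`min_expected` into its left neighbour; class 0 can only absorb
rightward) until every class reaches `min_expected` (default 1.0,
configurable). Degrees of freedom are `classes − 1 − 2` since two
parameters were estimated; fewer than 4 pooled classes is an error rather
than a test with df < 1. Expected class masses always sum to N exactly
(pmf plus survival of the tail). Simulation at n = 1000 shows the test
holds its nominal 5% level (empirical type-I error ≈ 0.04–0.06 across
independent 200-replicate blocks).

## Demography

### Life-table convention

The life table is age-classified in 1-day steps with age 0 the day of egg
deposition, and uses the classic pivotal-age convention: row `x` describes
the day class `[x, x+1)`, `lx` is the fraction of the original female
cohort alive *during* that day (survivorship evaluated at the midpoint age
`x + 0.5`), and `mx` is the female eggs laid per living female during that
day. Under this convention a cohort whose adults all live exactly `L` days
with constant daily fecundity `m` has `R0 = L·m` exactly; evaluating `lx`
at integer ages instead would bias `R0` by half a day of reproduction in
either direction depending on when eggs are credited.

### Expected-cohort construction

`build_life_table` turns a stage schedule into a deterministic expected
cohort under three parameter-explicit assumptions:

1. **Stage transitions** sit at the rounded cumulative mean stage
   durations (egg → three nymphal instars → adult).
2. **Stage survival** multiplies `lx` down at each stage completion.
   Default 1.0 per stage: the rearing counts that calibrate the default
   schedule are sample sizes per stage, not survival fractions, and no
   separate egg-to-adult survival estimate is available; users with
   mortality data set `stage_survival` explicitly.
3. **Adult survivorship** declines linearly from emergence to twice the
   mean adult female lifespan, which makes the mean lifespan exact. When
   the lifespan SD is zero the cohort instead dies exactly at the mean
   (rectangular survivorship) — the known distribution is then honored
   rather than the linear stand-in, and this is what makes the
   deterministic simulated cohort reproduce the analytic `lx` column
   exactly.

`mx = eggs_per_female_day × female_fraction` on every day an adult female
can be alive. The per-day rate is the primary fecundity parameter; the
lifetime egg count is carried as a reported diagnostic because rate ×
mean lifespan and the lifetime mean need not agree in rearing data (they
do not in the calibrating dataset: 0.35 × 15.0 = 5.25 vs 6.1).

### Default (calibrated) schedule

`hoopoe_schedule()` encodes in vitro rearing of the hoopoe louse at
35 ± 1 °C, 75–82 % RH on a feather diet: stage durations (mean ± SD,
range, days) egg 5.25 ± 0.97 (4–7), nymph I 5.08 ± 0.85 (4–7), nymph II
5.54 ± 0.84 (4–7), nymph III 6.04 ± 1.89 (5–7); adult lifespans female
15.0 ± 6.28 (2–24), male 10.96 ± 3.92 (1–21); fecundity 0.35 egg/♀/day
(6.1 eggs/lifetime); adult sex ratio 1 ♂ : 1.3 ♀, hence a female egg
fraction of 1.3/2.3 ≈ 0.565. With default survival this yields
R0 ≈ 2.97 female eggs/female, rm ≈ 0.0355/day, T ≈ 30.7 d, DT ≈ 19.5 d.

### Euler–Lotka solution

`rm` is the root of `f(r) = Σ_x e^(−r·x) lx mx − 1`. On any table with
reproduction at a positive age, `f` is strictly decreasing, so the real
root is unique; it is found by geometric bracket expansion from `[−2, 2]`
followed by Brent's method (xtol 10⁻¹⁴), and the returned root's residual
must be below `tol` (default 10⁻¹⁰) or an error is raised. A point-mass
table (all reproduction at a single age `a`) short-circuits to the closed
form `ln(R0)/a`. Derived parameters use natural logarithms throughout:
`T = ln(R0)/rm`, `DT = ln 2 / rm`, `λ = e^rm`; `T` is undefined at
`rm = 0` (where it tends to the cohort's mean age of reproduction) and
`DT` requires `rm > 0` — both are errors, not silent zeros.

## Synthetic data

- **Host counts** come from the gamma-mixed Poisson: each host draws a
  gamma(shape k, mean m) expected load and then a Poisson count, the
  standard mechanistic route to negative-binomial aggregation.
- **The census fixture** (`hoopoe_census`) produces a 30-host vector with
  exactly 12 infested hosts, positive counts within 7–83, summing to
  exactly 468 (Dirichlet weights, largest-remainder rounding, bound
  repair), so the descriptive triple 40% / 39.0 / 15.6 holds for every
  seed while the split over hosts varies. It is a synthetic test fixture
  emulating an unpublished census, not a reconstruction of the real birds.
- **Rearing cohorts** draw stage durations from normals truncated to each
  stage's hard range (truncated normal chosen because rearing data are
  reported as mean ± SD with ranges; a discretized gamma would hide the
  reported parameters), kill individuals in each stage with probability
  `1 − stage_survival` (death at the failed molt, i.e. at the end of the
  drawn stage duration), sex individuals at the egg stage, draw
  sex-specific truncated-normal adult lifespans, and give surviving
  females Poisson egg counts with mean `rate × lifespan`.
- **Empirical life tables** (`cohort_to_life_table`) track the female
  cohort: `lx` from death ages at day-class midpoints, `mx` from each
  female's eggs spread uniformly over her adult lifespan, times the female
  egg fraction (defaulting to the cohort's own observed sex ratio).

All generators are pure functions of (parameters, seed).

What the simulator does *not* emulate: transmission between hosts,
seasonal dynamics, host mortality or grooming, density dependence on a
host, or any correlation between a host's louse load and louse fitness.
Passing tests therefore demonstrate internal consistency of the methods at
the study's parameter values, not fidelity to any particular wild
population.

## Numerical choices and degenerate inputs

- Empty host vectors, all-zero counts (for D and the ML fit), no-female
  cohorts, `R0 = 0` tables, `rm ≤ 0` doubling times, and too-small
  `max_age` all raise informative errors instead of returning sentinels.
- `max_age` must cover development plus the full adult reproductive span
  so `R0` is never silently truncated.
- Chi-square class labels are plain strings (`"0"`, `"5-9"`, `">=10"`),
  stable across runs.
- Reports isolate the timestamp in a single field; everything else is
  byte-reproducible for identical inputs, seed and configuration, and is
  validated against the versioned schema in `lousepop/schemas/`.

## Problem sizes used in validation

Estimator recovery uses 50 seeded samples of n = 500 per k ∈ {0.12, 0.5,
2}; chi-square calibration 200 replicates at n = 1000; solver
verification 100 random life tables against a 10⁻⁵-step grid scan on
[−1, 1]; moment convergence of the count generator n = 10⁵; cross-module
demographic consistency a 10⁴-individual cohort. These sizes give
comfortable Monte-Carlo margins for the tolerances tested (e.g. the
median-|k̂−k|/k criterion of 20% is met with observed medians around 6%).

## Known limitations

- The ML fit profiles the likelihood with the mean fixed at the sample
  mean; joint (mean, k) ML differs negligibly for these sample sizes but
  is not implemented.
- The expected-cohort life table is deterministic; variance of `rm`
  (stochastic demography) and the stable age distribution are out of
  scope.
- The linear adult-survivorship decline is a two-parameter stand-in that
  honors only the mean lifespan, not the full lifespan distribution; with
  rearing-level lifespan data, feed an empirical life table directly
  (`demography --life-table`) to bypass it.
- No confidence intervals on prevalence/intensity or bootstrap machinery;
  the package reports point estimates and fit diagnostics only.
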