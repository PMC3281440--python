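"""Seeded generators emulating the study's two raw datasets.

The raw records behind a host census (which bird carried how many lice) and
an in vitro rearing experiment (per-individual stage durations, deaths,
egg output) are rarely deposited.  This module generates statistically
faithful stand-ins so every pipeline stage is testable end to end:

* ``simulate_host_counts`` — overdispersed per-host counts from the
  gamma-mixed Poisson (negative binomial) model;
* ``hoopoe_census`` — a constrained 30-host census fixture reproducing the
  published descriptive triple exactly (12 infested hosts, 468 lice total,
  every positive count within 7-83);
* ``simulate_rearing_cohort`` — individual-based rearing records with
  truncated-normal stage durations, per-stage mortality, sexing and
  Poisson egg output;
* ``cohort_to_life_table`` — the empirical life table of a simulated
  cohort, closing the loop with the demography module.

All generators are pure functions of (parameters, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .aggregation import HostCounts
from .demography import Duration, LifeTable, StageSchedule

__all__ = [
    "RearingRecord",
    "simulate_host_counts",
    "hoopoe_census",
    "simulate_rearing_cohort",
    "cohort_to_life_table",
]


@dataclass(frozen=True)
class RearingRecord:
    """One individual's in vitro rearing history.

    ``stage_durations`` holds only stages the individual completed;
    ``died_in_stage`` names the stage it failed (None if it reached
    adulthood and died as an adult).  ``death_age`` is the age at death in
    days from egg deposition.  ``eggs_laid`` is zero for males and for
    females that never reached adulthood.
    """

    individual_id: str
    sex: str  # "female" | "male"
    stage_durations: dict[str, float] = field(default_factory=dict)
    died_in_stage: Optional[str] = None
    adult_lifespan: Optional[float] = None
    eggs_laid: int = 0
    death_age: float = 0.0

    @property
    def reached_adulthood(self) -> bool:
        return self.died_in_stage is None


def simulate_host_counts(
    n_hosts: int, mean: float, k: float, seed: int
) -> HostCounts:
    """Draw per-host counts from a negative binomial via gamma-mixed Poisson.

    Each host gets a gamma(shape=k, mean=mean) expected load, then a Poisson
    count around it — the standard mechanistic route to aggregated parasite
    distributions.  Marginal mean is ``mean``; variance-to-mean ratio is
    ``1 + mean/k``.
    """
    if n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    if mean <= 0 or k <= 0:
        raise ValueError("mean and k must be positive")
    rng = np.random.default_rng(seed)
    lam = rng.gamma(shape=k, scale=mean / k, size=n_hosts)
    counts = rng.poisson(lam)
    ids = tuple(f"host{i + 1:03d}" for i in range(n_hosts))
    return HostCounts(counts, ids)


_CENSUS_N = 30
_CENSUS_INFESTED = 12
_CENSUS_TOTAL = 468
_CENSUS_LO, _CENSUS_HI = 7, 83


def hoopoe_census(seed: int) -> HostCounts:
    """A 30-host census fixture with the published summary statistics.

    Exactly 12 hosts are infested, positive counts lie in [7, 83] and sum
    to exactly 468, so prevalence = 0.40, mean intensity = 39.0 and mean
    abundance = 15.6 by construction.  The split of the 468 lice over the
    12 hosts is seed-dependent (Dirichlet weights + largest-remainder
    rounding + bound repair); this is a synthetic test fixture emulating an
    unpublished census, not a claim about the real birds.
    """
    rng = np.random.default_rng(seed)
    n_pos = _CENSUS_INFESTED
    surplus = _CENSUS_TOTAL - _CENSUS_LO * n_pos  # lice beyond the floor of 7 each

    # aggregated-looking weights, then largest-remainder rounding to the total
    w = rng.dirichlet(np.full(n_pos, 0.6))
    raw = w * surplus
    extra = np.floor(raw).astype(int)
    remainder = raw - extra
    short = surplus - int(extra.sum())
    for i in np.argsort(-remainder, kind="stable")[:short]:
        extra[i] += 1
    vals = _CENSUS_LO + extra

    # repair upper-bound violations by shifting excess onto the smallest hosts
    while vals.max() > _CENSUS_HI:
        hi = int(np.argmax(vals))
        lo = int(np.argmin(vals))
        shift = min(vals[hi] - _CENSUS_HI, _CENSUS_HI - vals[lo])
        vals[hi] -= shift
        vals[lo] += shift

    counts = np.zeros(_CENSUS_N, dtype=np.int64)
    positions = rng.choice(_CENSUS_N, size=n_pos, replace=False)
    counts[positions] = vals
    ids = tuple(f"bird{i + 1:02d}" for i in range(_CENSUS_N))
    return HostCounts(counts, ids)


def _draw_duration(rng: np.random.Generator, d: Duration, size: int) -> np.ndarray:
    """Truncated-normal durations; degenerate at the mean when sd = 0."""
    if d.min_days > d.max_days:
        raise ValueError("impossible truncation bounds")
    if d.sd == 0:
        return np.full(size, d.mean)
    a = (d.min_days - d.mean) / d.sd
    b = (d.max_days - d.mean) / d.sd
    return stats.truncnorm.rvs(a, b, loc=d.mean, scale=d.sd, size=size, random_state=rng)


def simulate_rearing_cohort(
    schedule: StageSchedule, n: int, seed: int
) -> list[RearingRecord]:
    """Simulate ``n`` individuals reared from freshly laid eggs.

    Per individual: stage durations drawn from the truncated normal of each
    stage, death in each stage with probability ``1 - stage_survival``
    (death occurs at the end of the drawn stage duration — the failed
    molt), sex female with probability ``female_fraction``, sex-specific
    truncated-normal adult lifespan, and for surviving females a Poisson
    egg count with mean ``eggs_per_female_day * lifespan``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)

    durations = {
        st.name: _draw_duration(rng, st.duration, n) for st in schedule.stages
    }
    dies = {
        st.name: rng.random(n) >= schedule.stage_survival.get(st.name, 1.0)
        for st in schedule.stages
    }
    is_female = rng.random(n) < schedule.female_fraction
    life_f = _draw_duration(rng, schedule.adult_female_lifespan, n)
    life_m = _draw_duration(rng, schedule.adult_male_lifespan, n)
    lifespan = np.where(is_female, life_f, life_m)
    eggs = rng.poisson(schedule.eggs_per_female_day * lifespan)

    records: list[RearingRecord] = []
    width = len(str(n))
    for i in range(n):
        sex = "female" if is_female[i] else "male"
        completed: dict[str, float] = {}
        age = 0.0
        died_in: Optional[str] = None
        for st in schedule.stages:
            dur = float(durations[st.name][i])
            age += dur
            if dies[st.name][i]:
                died_in = st.name
                break
            completed[st.name] = dur
        if died_in is None:
            span = float(lifespan[i])
            age += span
            records.append(
                RearingRecord(
                    individual_id=f"ind{i + 1:0{width}d}",
                    sex=sex,
                    stage_durations=completed,
                    died_in_stage=None,
                    adult_lifespan=span,
                    eggs_laid=int(eggs[i]) if is_female[i] else 0,
                    death_age=age,
                )
            )
        else:
            records.append(
                RearingRecord(
                    individual_id=f"ind{i + 1:0{width}d}",
                    sex=sex,
                    stage_durations=completed,
                    died_in_stage=died_in,
                    adult_lifespan=None,
                    eggs_laid=0,
                    death_age=age,
                )
            )
    return records


def cohort_to_life_table(
    records: Sequence[RearingRecord],
    step: float = 1.0,
    female_fraction: Optional[float] = None,
) -> LifeTable:
    """Empirical female-based life table of a simulated cohort.

    ``lx`` is the fraction of the female cohort alive during each day class
    (midpoint convention, matching the analytic table); ``mx`` is the
    observed eggs per living female per day — each female's eggs spread
    uniformly over her adult lifespan — times the fraction of eggs that are
    female.  That fraction defaults to the cohort's own observed adult sex
    ratio; pass ``female_fraction`` to override.
    """
    if not records:
        raise ValueError("empty cohort")
    females = [r for r in records if r.sex == "female"]
    if not females:
        raise ValueError("cohort contains no females; mx undefined")
    if female_fraction is None:
        female_fraction = len(females) / len(records)

    death = np.array([r.death_age for r in females])
    dev = np.array(
        [sum(r.stage_durations.values()) if r.reached_adulthood else np.inf
         for r in females]
    )
    rate = np.array(
        [r.eggs_laid / r.adult_lifespan
         if r.reached_adulthood and r.adult_lifespan and r.adult_lifespan > 0
         else 0.0
         for r in females]
    )

    n_steps = int(np.ceil(death.max() / step)) + 1
    x = np.arange(n_steps) * step
    mid = x + step / 2.0
    alive = death[None, :] > mid[:, None]
    adult = dev[None, :] <= mid[:, None]
    n_alive = alive.sum(axis=1)
    lx = n_alive / len(females)
    egg_rate = (alive & adult) @ rate  # total eggs/day laid during each day class
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(n_alive > 0, egg_rate * step * female_fraction / np.maximum(n_alive, 1), 0.0)
    return LifeTable(x=x, lx=lx, mx=mx)
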