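import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lousepop as lp

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def census():
    """A constrained 30-host census fixture (12 infested, 468 lice, 7-83)."""
    return lp.hoopoe_census(seed=20070)


@pytest.fixture
def schedule():
    """The rearing-calibrated default stage schedule."""
    return lp.hoopoe_schedule()


@pytest.fixture
def rectangular_schedule():
    """Deterministic schedule: 5+5+5+6 day stages, 10-day adult life, no deaths."""
    return lp.StageSchedule(
        stages=(
            lp.Stage("egg", lp.Duration(5, 0, 5, 5)),
            lp.Stage("nymph1", lp.Duration(5, 0, 5, 5)),
            lp.Stage("nymph2", lp.Duration(5, 0, 5, 5)),
            lp.Stage("nymph3", lp.Duration(6, 0, 6, 6)),
        ),
        adult_female_lifespan=lp.Duration(10, 0, 10, 10),
        adult_male_lifespan=lp.Duration(10, 0, 10, 10),
        eggs_per_female_day=0.4,
        lifetime_eggs_per_female=4.0,
        female_fraction=0.5,
        stage_survival={"egg": 1.0, "nymph1": 1.0, "nymph2": 1.0, "nymph3": 1.0},
    )


def random_life_table(rng: np.random.Generator) -> lp.LifeTable:
    """A random but valid life table with reproduction at positive ages."""
    first_repro = rng.integers(5, 25)
    last = first_repro + rng.integers(5, 20)
    x = np.arange(last + 1, dtype=float)
    drops = rng.uniform(0.9, 1.0, size=last + 1)
    lx = np.cumprod(drops)
    lx[0] = 1.0
    lx = np.minimum.accumulate(lx)
    mx = np.zeros(last + 1)
    mx[first_repro:] = rng.uniform(0.05, 0.6, size=last + 1 - first_repro)
    return lp.LifeTable(x=x, lx=lx, mx=mx)
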