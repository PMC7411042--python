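import numpy as np
import pytest

from lifedemog.life_table import IndividualRecord
from lifedemog.synthetic import CohortParams


def make_record(death_interval, offspring=(), censored=False, ident="i1",
                species="sp", temperature=20.0, census_interval=0.5):
    off = list(offspring) + [0] * (death_interval - len(offspring))
    return IndividualRecord(
        individual_id=ident,
        species=species,
        temperature=temperature,
        death_interval=death_interval,
        offspring=tuple(off[:death_interval]),
        censored=censored,
        census_interval=census_interval,
    )


@pytest.fixture
def two_individual_cohort():
    """One dies in interval 2, one in interval 3; each has 1 offspring in
    interval 2.  Hand-computed: lx = [1, 1, 0.5], mx = [0, 1, 0]."""
    return [
        make_record(2, offspring=(0, 1), ident="a"),
        make_record(3, offspring=(0, 1, 0), ident="b"),
    ]


@pytest.fixture
def reproductive_params():
    """A realistic rotifer-like schedule at a 12-h census: maturation
    after ~3 days, then about one neonate per half-day, with a modest
    constant hazard."""
    return CohortParams(
        species="demo",
        temperature=20.0,
        n_individuals=24,
        q=(0.05,),
        fecundity=(0, 0, 0, 0, 0, 0, 1.0, 1.0, 1.0, 1.0),
        max_intervals=400,
    )


def random_cohort_table(rng, max_len=30):
    """A random valid (x, lx, mx) schedule with guaranteed reproduction
    at some positive age."""
    from lifedemog.life_table import CohortTable

    n = int(rng.integers(3, max_len))
    step = float(rng.choice([0.5, 1.0]))
    q = rng.uniform(0.0, 0.4, size=n - 1)
    lx = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    mx = rng.uniform(0.0, 3.0, size=n) * (rng.random(n) < 0.7)
    mx[0] = 0.0
    j = int(rng.integers(1, n))
    mx[j] = max(mx[j], 0.5)  # reproduction at a positive age
    x = np.arange(n) * step
    return CohortTable(x=x, lx=lx, mx=mx, n0=24, census_interval=step)


def bisection_solve(table, lo=-50.0, hi=50.0, tol=1e-12):
    """Independent brute-force bisection on the renewal residual."""
    import math

    def f(r):
        w = table.lx * table.mx
        mask = w > 0
        expo = np.clip(-r * table.x[mask], -700, 700)
        return float(np.sum(np.exp(expo) * w[mask]) - 1.0)

    f_lo, f_hi = f(lo), f(hi)
    assert f_lo > 0 > f_hi, "oracle bracket does not straddle the root"
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
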