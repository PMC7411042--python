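"""Cohort life tables from individual-level census records.

The experimental unit is a single female followed from birth (age 0) at a
fixed census interval (12 h by default) until death.  At each census the
observer records whether she is still alive and how many neonates she
produced since the previous census.  From a cohort of such records this
module builds the classical life-table schedule:

* ``x``  — age at the start of each interval, in days,
* ``lx`` — survivorship: proportion of the initial cohort alive at the
  start of interval ``x``,
* ``mx`` — age-specific fecundity: offspring produced during the interval
  per female alive at its start.

Conventions (all configurable where it matters):

* Death is interval-censored: an individual scored dead at census ``j`` is
  assigned a lifespan of ``j * census_interval`` days (end of its death
  interval).
* The ``mx`` denominator is the number of females alive at the *start* of
  the interval; females dying within an interval still contribute any
  offspring observed at its closing census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndividualRecord",
    "CohortTable",
    "build_life_table",
    "average_lifespan",
    "aggregate_daily",
    "records_to_frame",
    "frame_to_records",
    "read_records_csv",
    "write_records_csv",
]


class LifeTableError(ValueError):
    """Invalid input to a life-table computation."""


@dataclass(frozen=True)
class IndividualRecord:
    """One female's complete life history at census resolution.

    Parameters
    ----------
    individual_id : str
        Unique label within the cohort.
    species : str
        Species (or clone) label of the treatment group.
    temperature : float
        Treatment temperature in degrees Celsius.
    death_interval : int
        1-based index of the census interval in which death was observed
        (or, for censored individuals, the last interval observed alive).
    offspring : tuple of int
        Offspring counted at each census, indexed by interval (1-based
        interval ``j`` is ``offspring[j - 1]``).  Entries beyond
        ``death_interval`` must be zero.
    censored : bool
        True if the individual was still alive when observation stopped.
    census_interval : float
        Length of one census interval in days (0.5 = 12 h).
    """

    individual_id: str
    species: str
    temperature: float
    death_interval: int
    offspring: tuple[int, ...]
    censored: bool = False
    census_interval: float = 0.5

    def __post_init__(self) -> None:
        if self.death_interval < 1:
            raise LifeTableError(
                f"death_interval must be >= 1, got {self.death_interval}"
            )
        off = tuple(int(o) for o in self.offspring)
        object.__setattr__(self, "offspring", off)
        if any(o < 0 for o in off):
            raise LifeTableError("offspring counts must be non-negative")
        if any(o != 0 for o in off[self.death_interval:]):
            raise LifeTableError(
                "offspring recorded after the death interval must be zero"
            )

    @property
    def lifespan_days(self) -> float:
        """Age at death (end of the death interval), in days."""
        return self.death_interval * self.census_interval

    @property
    def total_offspring(self) -> int:
        return int(sum(self.offspring))


@dataclass(frozen=True)
class CohortTable:
    """The (x, lx, mx) schedule of one homogeneous cohort.

    ``x`` holds interval start ages in days, ``lx`` the survivorship at
    each start, ``mx`` the per-capita fecundity of the interval, and
    ``n0`` the initial cohort size.
    """

    x: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    n0: int
    census_interval: float = 0.5

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        lx = np.asarray(self.lx, dtype=float)
        mx = np.asarray(self.mx, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "lx", lx)
        object.__setattr__(self, "mx", mx)
        if not (len(x) == len(lx) == len(mx)):
            raise LifeTableError("x, lx, mx must have equal lengths")
        if len(x) == 0:
            raise LifeTableError("empty life table")
        # lx[0] = 1 for tables built from records; schedules entered
        # directly (e.g. truncated to reproductive ages) may start lower
        if lx[0] > 1 + 1e-12 or lx[0] <= 0:
            raise LifeTableError("lx must start in (0, 1]")
        if np.any(np.diff(lx) > 1e-12):
            raise LifeTableError("lx must be non-increasing")
        if np.any(lx < -1e-12) or np.any(lx > 1 + 1e-12):
            raise LifeTableError("lx must lie in [0, 1]")
        if np.any(mx < 0):
            raise LifeTableError("mx must be non-negative")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "lx": self.lx, "mx": self.mx})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_life_table(
    records: Sequence[IndividualRecord],
    *,
    allow_censored: bool = False,
) -> CohortTable:
    """Build the cohort (x, lx, mx) schedule from individual records.

    ``lx[j] = (alive at start of interval j+1) / n0`` and
    ``mx[j] = (offspring in interval j+1) / (alive at its start)``.  The
    table extends to the last interval with at least one survivor at its
    start.

    Censored records are rejected unless ``allow_censored`` is set, in
    which case the table is truncated at the last interval fully observed
    for every individual.
    """
    if not records:
        raise LifeTableError("cannot build a life table from zero records")
    group = {(rec.species, rec.temperature) for rec in records}
    if len(group) > 1:
        raise LifeTableError(
            f"records span multiple (species, temperature) groups: {sorted(group)}"
        )
    steps = {rec.census_interval for rec in records}
    if len(steps) > 1:
        raise LifeTableError("records mix census intervals")
    census_interval = steps.pop()

    censored = [r for r in records if r.censored]
    if censored and not allow_censored:
        raise LifeTableError(
            f"{len(censored)} censored record(s); pass allow_censored=True "
            "to truncate the table at the shortest censoring time"
        )

    n0 = len(records)
    # last interval with a survivor at its start
    n_intervals = max(r.death_interval for r in records)
    if censored:
        n_intervals = min(n_intervals, min(r.death_interval for r in censored))

    death = np.array([r.death_interval for r in records])
    # alive at start of interval j = those whose death interval is >= j
    died_at = np.bincount(death, minlength=n_intervals + 1)[1:n_intervals + 1]
    alive = (n0 - np.concatenate([[0], np.cumsum(died_at)[:-1]])).astype(float)
    births = np.zeros(n_intervals, dtype=float)
    for rec in records:
        upto = min(len(rec.offspring), n_intervals)
        births[:upto] += np.asarray(rec.offspring[:upto], dtype=float)

    lx = alive / n0
    with np.errstate(invalid="ignore"):
        mx = np.where(alive > 0, births / np.maximum(alive, 1), 0.0)
    x = np.arange(n_intervals, dtype=float) * census_interval
    return CohortTable(x=x, lx=lx, mx=mx, n0=n0, census_interval=census_interval)


def average_lifespan(records: Sequence[IndividualRecord]) -> float:
    """Mean lifespan in days; death is placed at the end of its interval."""
    if not records:
        raise LifeTableError("cannot average zero records")
    if any(r.censored for r in records):
        raise LifeTableError("average_lifespan requires fully observed records")
    return float(np.mean([r.lifespan_days for r in records]))


def aggregate_daily(table: CohortTable) -> CohortTable:
    """Coarsen a sub-daily table to whole-day intervals.

    ``lx`` is taken at day starts; ``mx`` sums the offspring-per-survivor
    contributions of the constituent sub-intervals (offspring of a day per
    female alive at the start of each sub-interval, accumulated).  With a
    12-h census each day pools two intervals.
    """
    per_day = int(round(1.0 / table.census_interval))
    if per_day <= 1:
        return table
    n_days = int(np.ceil(len(table) / per_day))
    lx = table.lx[::per_day]
    x = table.x[::per_day]
    mx = np.zeros(n_days)
    for d in range(n_days):
        seg = slice(d * per_day, (d + 1) * per_day)
        # births per initial female over the day, re-normalised by survivors
        # at the day start so that lx*mx is conserved
        if table.lx[d * per_day] > 0:
            mx[d] = float(
                np.sum(table.lx[seg] * table.mx[seg]) / table.lx[d * per_day]
            )
    return CohortTable(x=x, lx=lx, mx=mx, n0=table.n0, census_interval=1.0)


# ---------------------------------------------------------------------------
# record <-> tabular round-trip (CSV contract shared with the generator)

_CSV_COLUMNS = [
    "individual_id",
    "species",
    "temperature_C",
    "interval_index",
    "age_start_days",
    "alive_at_end",
    "offspring_count",
    "censored",
]


def records_to_frame(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Long-format frame: one row per individual x census interval."""
    rows = []
    for rec in records:
        n_int = max(rec.death_interval, len(rec.offspring))
        for j in range(1, n_int + 1):
            off = rec.offspring[j - 1] if j <= len(rec.offspring) else 0
            alive_at_end = int(j < rec.death_interval or (j == rec.death_interval and rec.censored))
            rows.append(
                (
                    rec.individual_id,
                    rec.species,
                    rec.temperature,
                    j,
                    (j - 1) * rec.census_interval,
                    alive_at_end,
                    off,
                    int(rec.censored and j == rec.death_interval),
                )
            )
            if j >= rec.death_interval:
                break
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame, *, census_interval: float | None = None) -> list[IndividualRecord]:
    """Rebuild :class:`IndividualRecord` objects from the long CSV format."""
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise LifeTableError(f"record frame is missing columns: {sorted(missing)}")
    records = []
    for ind, sub in frame.groupby("individual_id", sort=False):
        sub = sub.sort_values("interval_index")
        if census_interval is None:
            ages = sub["age_start_days"].to_numpy()
            step = float(ages[1] - ages[0]) if len(ages) > 1 else 0.5
        else:
            step = census_interval
        records.append(
            IndividualRecord(
                individual_id=str(ind),
                species=str(sub["species"].iloc[0]),
                temperature=float(sub["temperature_C"].iloc[0]),
                death_interval=int(sub["interval_index"].max()),
                offspring=tuple(int(v) for v in sub["offspring_count"]),
                censored=bool(sub["censored"].iloc[-1]),
                census_interval=step,
            )
        )
    return records


def write_records_csv(records: Sequence[IndividualRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[IndividualRecord]:
    return frame_to_records(pd.read_csv(path))
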