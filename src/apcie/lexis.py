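"""Lexis tables of deaths and person-years by age group and calendar year.

The central container is :class:`RateTable`: a complete grid of death
counts ``D`` and person-years ``N`` over closed five-year age intervals
(rows) and calendar years (columns).  Diagonals of the grid are birth
cohorts.  Only when the spacing between modelled periods equals the
age-interval width (five years) does each diagonal correspond to a true
five-year birth cohort; :func:`subsample_periods` produces such a grid
from an annual table, e.g. 1990, 1995, ..., 2015 from 1990-2015 data.

Open-ended age intervals ("85+") are rejected at read time: an
age-period-cohort decomposition needs every cell to map to a bounded
birth-year range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

AGE_WIDTH = 5
CSV_COLUMNS = ["age_start", "age_end", "year", "deaths", "population"]


@dataclass(frozen=True)
class RateTable:
    """Complete age x period grid of death counts and person-years.

    Parameters
    ----------
    age_groups
        Closed integer age intervals ``(start, end)`` with
        ``end - start + 1 == 5``, youngest first, contiguous.
    periods
        Calendar years, strictly ascending (not necessarily contiguous).
    deaths
        Integer-valued array of shape ``(n_age, n_period)``; ``deaths[i, j]``
        is the count for age group ``i`` in year ``periods[j]``.
    population
        Person-years at risk, same shape, strictly positive.
    """

    age_groups: tuple[tuple[int, int], ...]
    periods: tuple[int, ...]
    deaths: np.ndarray
    population: np.ndarray

    def __post_init__(self):
        ages = tuple((int(a), int(b)) for a, b in self.age_groups)
        periods = tuple(int(y) for y in self.periods)
        deaths = np.asarray(self.deaths, dtype=float)
        pop = np.asarray(self.population, dtype=float)
        object.__setattr__(self, "age_groups", ages)
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "population", pop)

        if not ages or not periods:
            raise ValidationError("table must have at least one age group and one period")
        shape = (len(ages), len(periods))
        if deaths.shape != shape or pop.shape != shape:
            raise ValidationError(
                f"deaths/population shape {deaths.shape}/{pop.shape} does not match "
                f"{len(ages)} age groups x {len(periods)} periods"
            )
        for a, b in ages:
            if b - a + 1 != AGE_WIDTH:
                raise ValidationError(
                    f"age interval [{a}, {b}] does not span {AGE_WIDTH} years; "
                    "open-ended or irregular intervals are not supported"
                )
        for (_, prev_end), (nxt_start, _) in zip(ages[:-1], ages[1:]):
            if nxt_start != prev_end + 1:
                raise ValidationError("age intervals must be contiguous and ascending")
        if any(b <= a for a, b in zip(periods[:-1], periods[1:])):
            raise ValidationError("periods must be strictly ascending")
        if not np.all(np.isfinite(pop)) or np.any(pop <= 0):
            raise ValidationError("population entries must be positive and finite")
        if np.any(deaths < 0):
            raise ValidationError("death counts must be nonnegative")
        if not np.allclose(deaths, np.round(deaths), atol=1e-9):
            raise ValidationError("death counts must be integers")
        if np.any(deaths > pop):
            raise ValidationError("death counts cannot exceed population")

    @property
    def n_age(self) -> int:
        return len(self.age_groups)

    @property
    def n_period(self) -> int:
        return len(self.periods)

    def age_labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.age_groups]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per (age group, year) cell."""
        rows = []
        for i, (a, b) in enumerate(self.age_groups):
            for j, y in enumerate(self.periods):
                rows.append((a, b, y, int(round(self.deaths[i, j])), self.population[i, j]))
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass(frozen=True)
class CohortLayout:
    """Index algebra mapping grid cells to birth-cohort diagonals.

    With ``i = 1`` the youngest age group and ``j = 1`` the earliest
    period, cell ``(i, j)`` lies on diagonal ``k = (A - i) + j``; there are
    ``C = A + P - 1`` diagonals, ordered from the oldest birth cohort
    (oldest age group in the earliest period) to the youngest.
    """

    n_age: int
    n_period: int
    n_cohort: int
    period_step: int
    cohort_labels: tuple[str, ...]

    def __post_init__(self):
        if self.n_cohort != self.n_age + self.n_period - 1:
            raise ValidationError("n_cohort must equal n_age + n_period - 1")


def cohort_index(n_age: int, i: int, j: int) -> int:
    """Diagonal index ``k = (A - i) + j`` for 1-based ``i`` (age) and ``j`` (period)."""
    return (n_age - i) + j


def cohort_label(
    layout: CohortLayout,
    k: int,
    earliest_period: int,
    oldest_age_interval: tuple[int, int],
) -> tuple[int, int]:
    """Closed birth-year range for cohort diagonal ``k``.

    Diagonal ``k = 1`` holds the oldest age group in the earliest period,
    so its members were born between ``earliest_period - age_end`` and
    ``earliest_period - age_start``; each subsequent diagonal shifts the
    range forward by the age-interval width.
    """
    if not 1 <= k <= layout.n_cohort:
        raise IndexError(f"cohort index {k} outside 1..{layout.n_cohort}")
    a_min, a_max = oldest_age_interval
    width = a_max - a_min + 1
    lo = earliest_period - a_max + width * (k - 1)
    hi = earliest_period - a_min + width * (k - 1)
    return (lo, hi)


def cohort_layout(table: RateTable) -> CohortLayout:
    """Build the cohort indexing for a table with uniformly spaced periods."""
    steps = np.diff(table.periods)
    if len(steps) and not np.all(steps == steps[0]):
        raise ValidationError("periods must be uniformly spaced to index cohorts")
    step = int(steps[0]) if len(steps) else AGE_WIDTH
    A, P = table.n_age, table.n_period
    C = A + P - 1
    layout = CohortLayout(A, P, C, step, cohort_labels=())
    labels = tuple(
        "{}-{}".format(*cohort_label(layout, k, table.periods[0], table.age_groups[-1]))
        for k in range(1, C + 1)
    )
    object.__setattr__(layout, "cohort_labels", labels)
    return layout


def read_rate_table(source) -> RateTable:
    """Read a long-format CSV into a validated :class:`RateTable`.

    Expects columns ``age_start, age_end, year, deaths, population`` and
    exactly one row per (age group, year) combination.  A missing
    ``age_end`` (or one that cannot be parsed as an integer) marks an
    open-ended age group such as "85+" and is rejected outright.
    """
    df = pd.read_csv(source)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"input is missing required columns: {missing}")

    age_end = pd.to_numeric(df["age_end"], errors="coerce")
    if age_end.isna().any():
        bad = df.loc[age_end.isna(), "age_start"].tolist()
        raise ValidationError(
            f"open-ended age group(s) starting at {bad}: every age interval must be a "
            "closed [a, a+4] range (open-ended groups such as 85+ cannot be modelled)"
        )
    df = df.assign(age_end=age_end.astype(int))

    if df.duplicated(["age_start", "year"]).any():
        raise ValidationError("duplicate (age group, year) rows in input")

    ages = sorted({(int(a), int(b)) for a, b in zip(df["age_start"], df["age_end"])})
    years = sorted(int(y) for y in df["year"].unique())
    grid = {(int(a), int(y)): (d, n) for a, _, y, d, n in df[CSV_COLUMNS].itertuples(index=False)}
    gaps = [(a, y) for a, _ in ages for y in years if (a, y) not in grid]
    if gaps:
        raise ValidationError(f"incomplete grid: missing (age_start, year) cells {gaps[:10]}")

    deaths = np.array([[grid[(a, y)][0] for y in years] for a, _ in ages], dtype=float)
    pop = np.array([[grid[(a, y)][1] for y in years] for a, _ in ages], dtype=float)
    return RateTable(tuple(ages), tuple(years), deaths, pop)


def write_rate_table(table: RateTable, target) -> None:
    """Write the canonical long CSV (inverse of :func:`read_rate_table`)."""
    table.to_frame().to_csv(target, index=False)


def subsample_periods(table: RateTable, start_year: int, step: int) -> RateTable:
    """Keep only the years ``start_year, start_year + step, ...``.

    With ``step = 5`` this implements single-year sampling five years
    apart, the spacing under which each grid diagonal is a genuine
    five-year birth cohort.
    """
    if start_year not in table.periods:
        raise ValidationError(f"start year {start_year} not present in table")
    if step <= 0:
        raise ValidationError("step must be positive")
    keep = [j for j, y in enumerate(table.periods)
            if y >= start_year and (y - start_year) % step == 0]
    if len(keep) < 2:
        raise ValidationError(
            f"subsampling from {start_year} by {step} retains {len(keep)} period(s); "
            "at least 2 are needed to estimate a trend"
        )
    return RateTable(
        table.age_groups,
        tuple(table.periods[j] for j in keep),
        table.deaths[:, keep],
        table.population[:, keep],
    )


def restrict_ages(table: RateTable, age_min: int, age_max: int) -> RateTable:
    """Keep only age groups fully inside the closed range [age_min, age_max]."""
    keep = [i for i, (a, b) in enumerate(table.age_groups) if a >= age_min and b <= age_max]
    if not keep:
        raise ValidationError(f"no age group lies inside [{age_min}, {age_max}]")
    return RateTable(
        tuple(table.age_groups[i] for i in keep),
        table.periods,
        table.deaths[keep, :],
        table.population[keep, :],
    )


def compute_rates(table: RateTable, scale: float = 1e5) -> np.ndarray:
    """Mortality rates ``scale * D / N``, same shape as the grid."""
    if scale <= 0:
        raise ValidationError("scale must be positive")
    return scale * table.deaths / table.population


def rates_frame(table: RateTable, scale: float = 1e5) -> pd.DataFrame:
    """Long-format rates, one row per cell, for CSV export."""
    rates = compute_rates(table, scale)
    rows = []
    for i, (a, b) in enumerate(table.age_groups):
        for j, y in enumerate(table.periods):
            rows.append((a, b, y, rates[i, j]))
    return pd.DataFrame(rows, columns=["age_start", "age_end", "year", "rate_per_100k"])


def aggregate_rate(table: RateTable, year: int, scale: float = 1e5) -> float:
    """Crude all-age rate for one year: ``scale * sum_i D_i / sum_i N_i``."""
    if year not in table.periods:
        raise KeyError(f"year {year} not present in table")
    j = table.periods.index(year)
    return float(scale * table.deaths[:, j].sum() / table.population[:, j].sum())


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio ``rate_b / rate_a`` of two crude rates (e.g. last year over first)."""
    if rate_a <= 0:
        raise ValidationError("fold change undefined for a nonpositive baseline rate")
    return rate_b / rate_a
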