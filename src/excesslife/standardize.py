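"""Direct age standardization of mortality and the calendar corrections.

The central quantity is the directly standardized mortality rate (SMR)

    m^{y,s} = sum_i m_i^y * P_i^s / P^s,      m_i^y = D_i^y / P_i^y,

the weighted mean of age-specific death rates using the age structure of a
fixed reference year ``s`` (January 1 population).  Its variance on the log
scale follows from first-order (delta-method) propagation of independent
Poisson death counts:

    V[log m^{y,s}] = sum_i D_i (P_i^s / P_i^y)^2 / (sum_i D_i P_i^s / P_i^y)^2.

When ``y = s`` the SMR reduces exactly to the crude rate sum(D)/sum(P) and
the variance to 1/sum(D).  Standardized weekly deaths (SWD) rescale weekly
death counts per coarse age class to the reference population, making
weekly series comparable across years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelSchemaError, subset


class DegenerateRateError(ValueError):
    """A rate with zero deaths cannot support log-scale inference."""


class IncompleteDataError(ValueError):
    """A weekly table is missing weeks required by the operation."""


@dataclass(frozen=True)
class StandardizedRate:
    """A crude or standardized mortality rate with its log-scale variance.

    ``value`` is in deaths per person-year.  ``var_log`` is the delta-method
    variance of log(value); it is ``nan`` for degenerate (zero-death) rates,
    which cannot enter any confidence-interval computation.  ``source``
    records whether the rate is observed or predicted from a trend model.
    """

    value: float
    var_log: float
    sex: object
    year: int
    ref_year: int
    age_range: tuple[float, float] | None = None
    source: str = "observed"

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("rate value must be non-negative")
        if self.source not in ("observed", "predicted"):
            raise ValueError("source must be 'observed' or 'predicted'")

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.var_log)


@dataclass
class WeeklyDeathTable:
    """Weekly death counts by coarse age class, with companion populations.

    ``deaths`` has columns (year, week, age_class, deaths); ``populations``
    has (year, age_class, population) giving the January-1 class sizes for
    every year needed (including the standardization reference year).
    Age-class labels are strings such as "0-19" or "80+".
    """

    deaths: pd.DataFrame
    populations: pd.DataFrame

    def __post_init__(self):
        for col in ("year", "week", "age_class", "deaths"):
            if col not in self.deaths.columns:
                raise PanelSchemaError(f"weekly deaths table missing column {col!r}")
        for col in ("year", "age_class", "population"):
            if col not in self.populations.columns:
                raise PanelSchemaError(f"weekly populations table missing column {col!r}")

    def weeks(self, year: int) -> np.ndarray:
        return np.sort(self.deaths.loc[self.deaths["year"] == year, "week"].unique())

    def classes(self) -> list[str]:
        return list(self.deaths["age_class"].unique())


def leap_adjust(panel: pd.DataFrame, leap_years: set[int] | frozenset[int]) -> pd.DataFrame:
    """Exclude 1/366 of deaths in leap years (multiply by 365/366).

    Aligns leap years with 365-day years so annual rates are comparable.
    Years not in ``leap_years`` are untouched; an empty set is a no-op.
    """
    out = panel.copy()
    mask = out["year"].isin(leap_years)
    out.loc[mask, "deaths"] = out.loc[mask, "deaths"] * (365.0 / 366.0)
    return out


def weekly_to_annual(weekly: WeeklyDeathTable, year: int,
                     lead_fraction: float = 2.0 / 7.0,
                     tail_fraction: float = 1.0 / 7.0) -> pd.Series:
    """Aggregate weekly deaths of one year to annual per-class totals.

    Statistical weeks rarely align with the calendar year; the totals are
    corrected by adding ``lead_fraction`` of the first week's deaths and
    removing ``tail_fraction`` of the last week's.  The defaults 2/7 and 1/7
    align a 52-week year whose first week starts on January 3 and whose last
    week ends on January 1 of the next year.
    """
    if not (0 <= lead_fraction <= 1 and 0 <= tail_fraction <= 1):
        raise ValueError("boundary fractions must lie in [0, 1]")
    sub = weekly.deaths[weekly.deaths["year"] == year]
    if sub.empty:
        raise IncompleteDataError(f"no weekly data for year {year}")
    weeks = np.sort(sub["week"].unique())
    expected = np.arange(1, weeks[-1] + 1)
    if weeks[0] != 1 or not np.array_equal(weeks, expected):
        raise IncompleteDataError(
            f"year {year}: weeks present {weeks.tolist()} are not contiguous from 1")
    pivot = sub.pivot_table(index="age_class", columns="week", values="deaths",
                            aggfunc="sum", fill_value=0.0)
    total = pivot.sum(axis=1)
    total = total + lead_fraction * pivot[weeks[0]] - tail_fraction * pivot[weeks[-1]]
    total.name = "deaths"
    return total


def swd_series(weekly: WeeklyDeathTable, ref_year: int) -> pd.DataFrame:
    """Standardized weekly deaths: d^{w,y,s} = sum_k D_k^{w,y} P_k^s / P_k^y.

    Each class's weekly deaths are rescaled by the ratio of the reference
    population to the current population of that class, so the series is
    comparable across years despite population growth and ageing.
    """
    pops = weekly.populations.set_index(["year", "age_class"])["population"]
    if (pops <= 0).any():
        raise ValueError("class populations must be positive for standardization")
    ref = pops.xs(ref_year, level="year")
    rows = []
    for (year, week), grp in weekly.deaths.groupby(["year", "week"]):
        d = 0.0
        for _, rec in grp.iterrows():
            k = rec["age_class"]
            try:
                p_y = pops.loc[(year, k)]
            except KeyError:
                raise ValueError(f"missing population for class {k!r} in year {year}")
            d += rec["deaths"] * (ref.loc[k] / p_y)
        rows.append((int(year), int(week), d))
    return pd.DataFrame(rows, columns=["year", "week", "swd"]).sort_values(
        ["year", "week"], ignore_index=True)


def crude_rate(panel: pd.DataFrame, sex, year: int) -> StandardizedRate:
    """Crude mortality rate sum(D)/sum(P) with Poisson variance 1/sum(D) on
    the log scale.  Zero total deaths yield a degenerate rate (var_log nan)
    unusable in interval computations."""
    sub = subset(panel, sex=sex, year=year)
    if sub.empty:
        raise KeyError(f"no records for sex={sex!r}, year={year}")
    d = float(sub["deaths"].sum())
    p = float(sub["population"].sum())
    var_log = 1.0 / d if d > 0 else float("nan")
    return StandardizedRate(value=d / p, var_log=var_log, sex=sex, year=year,
                            ref_year=year, source="observed")


def standardized_rate(panel: pd.DataFrame, sex, year: int, ref_year: int,
                      age_range: tuple[float, float] | None = None) -> StandardizedRate:
    """Directly standardized mortality rate with delta-method log variance.

    Weights are the reference-year age distribution, renormalized within
    ``age_range`` when one is given (as used for age-class-stratified
    excess).  The computation is arranged as
    ``sum(D_i * w_i) / P^s`` with ``w_i = P_i^s / P_i^y`` so that at
    ``year == ref_year`` the result equals the crude rate exactly.
    """
    cur = subset(panel, sex=sex, year=year, age_range=age_range)
    ref = subset(panel, sex=sex, year=ref_year, age_range=age_range)
    if cur.empty or ref.empty:
        raise KeyError(f"no records for sex={sex!r} in year {year} or {ref_year}")
    cur = cur.set_index("age").sort_index()
    ref = ref.set_index("age").sort_index()
    if not cur.index.equals(ref.index):
        raise PanelSchemaError(
            f"age supports differ between year {year} and reference {ref_year}")
    d = cur["deaths"].to_numpy(dtype=float)
    w = ref["population"].to_numpy(dtype=float) / cur["population"].to_numpy(dtype=float)
    p_ref = float(ref["population"].sum())
    # weight conservation: within-range reference weights sum to one
    assert np.isclose((ref["population"] / p_ref).sum(), 1.0)
    weighted = d * w
    num = float(weighted.sum())
    value = num / p_ref
    if num > 0:
        var_log = float((d * w ** 2).sum()) / num ** 2
    else:
        var_log = float("nan")
    return StandardizedRate(value=value, var_log=var_log, sex=sex, year=year,
                            ref_year=ref_year, age_range=age_range, source="observed")
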