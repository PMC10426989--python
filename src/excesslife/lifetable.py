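"""Period life expectancy via a piecewise-exponential (constant-hazard) model.

Death rates are pooled into 19 five-year age classes (0-4, 5-9, ..., 85-89,
90+) and the hazard is assumed constant within each class.  Under that
assumption the period life expectancy at a start age ``a`` has the closed
form

    e_a = 1/2 + sum_{l=a}^{110} exp( - sum_{i=a}^{l} mdot_i ),

where ``mdot_i`` is the class rate of the class containing single age ``i``
(ages 90-110 all use the open 90+ rate).  Each term of the outer sum is the
probability of surviving past age ``l``; the leading 1/2 is the half year
lived on average in the year of death.  A hypothetical cohort exposed to a
single year's rates for life — the usual period interpretation.

Life expectancy losses between two years, or between an observed year and
its trend-predicted counterfactual, are reported in months (12 * the
difference in years; negative values are losses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import subset
from .trend import PoissonTrendModel

#: lower bounds of the 19 five-year classes, last one open (90+)
LIFE_TABLE_EDGES = tuple(range(0, 95, 5))
#: the oldest single age entering the life-table sum
MAX_AGE = 110


@dataclass(frozen=True)
class LifeTableResult:
    """Life expectancy at a start age under one year's class rates."""

    sex: object
    year: int
    start_age: int
    expectancy: float
    class_rates: tuple
    source: str = "observed"

    def __post_init__(self):
        if self.start_age not in (0, 50):
            raise ValueError("start_age must be 0 or 50")
        if any(r < 0 for r in self.class_rates):
            raise ValueError("class rates must be non-negative")


def class_rates(panel: pd.DataFrame, sex, year: int,
                edges=LIFE_TABLE_EDGES) -> np.ndarray:
    """Observed per-class rates: pooled deaths over pooled person-years."""
    sub = subset(panel, sex=sex, year=year)
    if sub.empty:
        raise KeyError(f"no records for sex={sex!r}, year={year}")
    edges_arr = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges_arr, sub["age"].to_numpy(), side="right") - 1
    deaths = np.bincount(idx, weights=sub["deaths"].to_numpy(), minlength=len(edges))
    pop = np.bincount(idx, weights=sub["population"].to_numpy(), minlength=len(edges))
    if np.any(pop == 0):
        empty = [int(edges_arr[k]) for k in np.nonzero(pop == 0)[0]]
        raise ValueError(f"zero population in age class(es) starting at {empty}")
    return deaths / pop


def predicted_class_rates(fit: PoissonTrendModel, panel: pd.DataFrame, sex, year: int,
                          edges=LIFE_TABLE_EDGES) -> np.ndarray:
    """Class rates implied by the trend model for ``year``.

    Predicted single-age rates are averaged within each class with the
    *current year's* population weights (the exposures actually at risk that
    year), mirroring how observed class rates pool deaths over exposures.
    """
    if fit.sex != sex:
        raise ValueError(f"trend fit is for sex {fit.sex!r}, not {sex!r}")
    sub = subset(panel, sex=sex, year=year).set_index("age").sort_index()
    pred = fit.predict_age_rates(year).set_index("age").sort_index()
    if not sub.index.equals(pred.index):
        raise ValueError("trend fit and panel age supports differ")
    edges_arr = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges_arr, sub.index.to_numpy(), side="right") - 1
    pop = sub["population"].to_numpy(dtype=float)
    expected = pred["rate"].to_numpy() * pop
    num = np.bincount(idx, weights=expected, minlength=len(edges))
    den = np.bincount(idx, weights=pop, minlength=len(edges))
    if np.any(den == 0):
        raise ValueError("zero population in an age class")
    return num / den


def expand_rates(rates, start_age: int = 0, edges=LIFE_TABLE_EDGES) -> np.ndarray:
    """Step-function hazard by single age from start_age to the horizon."""
    rates = np.asarray(rates, dtype=float)
    edges_arr = np.asarray(edges, dtype=float)
    if rates.shape[0] != edges_arr.shape[0]:
        raise ValueError("one rate per age class required")
    if np.any(rates < 0):
        raise ValueError("class rates must be non-negative")
    ages = np.arange(start_age, MAX_AGE + 1)
    idx = np.minimum(np.searchsorted(edges_arr, ages, side="right") - 1,
                     len(rates) - 1)
    return rates[idx]


def life_expectancy(rates, sex=None, year: int | None = None, start_age: int = 0,
                    edges=LIFE_TABLE_EDGES, source: str = "observed") -> LifeTableResult:
    """Piecewise-exponential life expectancy at ``start_age`` (0 or 50)."""
    hazard = expand_rates(rates, start_age=start_age, edges=edges)
    survival = np.exp(-np.cumsum(hazard))
    e = 0.5 + float(survival.sum())
    return LifeTableResult(sex=sex, year=year if year is not None else -1,
                           start_age=start_age, expectancy=e,
                           class_rates=tuple(np.asarray(rates, dtype=float)),
                           source=source)


def life_expectancy_loss(e_y: LifeTableResult, e_ref: LifeTableResult) -> float:
    """Life expectancy change in months; negative = loss versus comparator."""
    if e_y.start_age != e_ref.start_age:
        raise ValueError("life expectancies start at different ages")
    if e_y.sex != e_ref.sex:
        raise ValueError("life expectancies are for different sexes")
    return 12.0 * (e_y.expectancy - e_ref.expectancy)
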