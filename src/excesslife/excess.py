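"""Excess mortality (%) and excess deaths, with delta-method intervals.

Excess mortality compares a standardized rate observed in year ``y`` with a
comparator rate: either the rate of a past reference year ``z`` (the
"level" comparator) or the rate predicted for ``y`` by the pre-pandemic
trend model (the "trend" comparator).  In both cases

    EM = 100 * (m_y / m_comp - 1)   [%]
    CI = 100 * exp{ log(m_y / m_comp) +- z * sqrt(V[log m_y] + V[log m_comp]) } - 100
    ED = (m_y - m_comp) * P^s       [deaths on the reference-population scale]

with the two log variances added because the underlying death counts (or
the fitted model and the current year's counts) are independent.  The
interval is symmetric on the log-ratio scale, hence asymmetric in %.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

from .panel import check_class_edges, subset
from .standardize import DegenerateRateError, StandardizedRate, standardized_rate
from .trend import PoissonTrendModel

#: normal quantile used for nominal 95% intervals, kept as the conventional
#: rounded constant rather than the exact quantile
Z_95 = 1.96


@dataclass(frozen=True)
class ExcessEstimate:
    """Excess mortality in % with CI, and excess deaths, for one comparison."""

    em_percent: float
    ci_low: float
    ci_high: float
    excess_deaths: float
    comparator: str           # "past_year(z)" or "trend"
    sex: object
    year: int
    age_range: tuple[float, float] | None = None
    nominal_level: float = 0.95

    def __post_init__(self):
        vals = (self.ci_low, self.em_percent, self.ci_high)
        if all(not math.isnan(v) for v in vals) and \
                not (self.ci_low <= self.em_percent <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")

    @property
    def undefined_ci(self) -> bool:
        return math.isnan(self.ci_low) or math.isnan(self.ci_high)

    @property
    def significant(self) -> bool:
        """True when the CI excludes zero excess."""
        return self.ci_low > 0 or self.ci_high < 0


def _excess(rate_y: StandardizedRate, rate_ref: StandardizedRate,
            ref_pop_total: float, comparator: str, z: float) -> ExcessEstimate:
    if rate_ref.value == 0 or rate_ref.degenerate or rate_y.degenerate:
        raise DegenerateRateError(
            "comparator rate is zero or a variance is undefined; no CI possible")
    ratio = rate_y.value / rate_ref.value
    half = z * math.sqrt(rate_y.var_log + rate_ref.var_log)
    em = 100.0 * ratio - 100.0
    lo = 100.0 * math.exp(math.log(ratio) - half) - 100.0
    hi = 100.0 * math.exp(math.log(ratio) + half) - 100.0
    ed = (rate_y.value - rate_ref.value) * ref_pop_total
    return ExcessEstimate(em_percent=em, ci_low=lo, ci_high=hi, excess_deaths=ed,
                          comparator=comparator, sex=rate_y.sex, year=rate_y.year,
                          age_range=rate_y.age_range)


def excess_vs_reference(rate_y: StandardizedRate, rate_z: StandardizedRate,
                        ref_pop_total: float, z: float = Z_95) -> ExcessEstimate:
    """Excess of year y over past year z, both standardized to the same
    reference population (level comparator)."""
    _check_pair(rate_y, rate_z, expected_source="observed")
    return _excess(rate_y, rate_z, ref_pop_total,
                   comparator=f"past_year({rate_z.year})", z=z)


def excess_vs_trend(rate_y: StandardizedRate, rate_hat: StandardizedRate,
                    ref_pop_total: float, z: float = Z_95) -> ExcessEstimate:
    """Excess of the observed year-y rate over its trend prediction.  The
    CI adds the model's delta-method variance to the Poisson term."""
    _check_pair(rate_y, rate_hat, expected_source="predicted")
    return _excess(rate_y, rate_hat, ref_pop_total, comparator="trend", z=z)


def _check_pair(rate_y: StandardizedRate, rate_ref: StandardizedRate,
                expected_source: str):
    if rate_y.source != "observed":
        raise ValueError("the year-under-study rate must be observed")
    if rate_ref.source != expected_source:
        raise ValueError(f"comparator rate must have source {expected_source!r}")
    if rate_y.sex != rate_ref.sex or rate_y.ref_year != rate_ref.ref_year \
            or rate_y.age_range != rate_ref.age_range:
        raise ValueError("rates must share sex, standardization year and age range")


def excess_by_age_class(panel: pd.DataFrame, sex, year: int,
                        comparator: int | PoissonTrendModel,
                        class_edges, ref_year: int,
                        z: float = Z_95) -> list[ExcessEstimate]:
    """Age-class-stratified excess with class-restricted SMRs.

    ``comparator`` is a past year (int) or a fitted trend model.  Each class
    uses reference weights renormalized within the class, so excess deaths
    sum exactly to the all-ages figure over any partition.  Classes whose
    comparator rate is degenerate are returned with NaN interval bounds
    rather than aborting the other classes.
    """
    edges = check_class_edges(class_edges)
    out: list[ExcessEstimate] = []
    ranges = [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]
    ranges.append((float(edges[-1]), float("inf")))
    for lo, hi in ranges:
        ref_pop = float(subset(panel, sex=sex, year=ref_year,
                               age_range=(lo, hi))["population"].sum())
        rate_y = standardized_rate(panel, sex, year, ref_year, age_range=(lo, hi))
        if isinstance(comparator, PoissonTrendModel):
            rate_ref = comparator.predict_standardized_rate(
                year, panel, ref_year, age_range=(lo, hi))
            builder, comp = excess_vs_trend, "trend"
        else:
            rate_ref = standardized_rate(panel, sex, int(comparator), ref_year,
                                         age_range=(lo, hi))
            builder, comp = excess_vs_reference, f"past_year({comparator})"
        try:
            out.append(builder(rate_y, rate_ref, ref_pop, z=z))
        except DegenerateRateError:
            ed = (rate_y.value - rate_ref.value) * ref_pop
            em = (100.0 * rate_y.value / rate_ref.value - 100.0
                  if rate_ref.value > 0 else float("nan"))
            out.append(ExcessEstimate(
                em_percent=em, ci_low=float("nan"), ci_high=float("nan"),
                excess_deaths=ed, comparator=comp, sex=sex, year=year,
                age_range=(lo, hi)))
    return out
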