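"""Synthetic mortality data with the structure the analysis assumes.

The generator emulates national vital-statistics extracts: per-sex death
counts by single year of age (top class open), January-1 population sizes
growing slowly from year to year, log-linear per-age declines in mortality
rates, and — for the most recent year — deaths available only weekly in
coarse age classes.  Counts are Poisson around the deterministic rate
surface

    m(i, y) = exp( base(i) + slope(i) * (y - midpoint) ) * shock(y, i),

where ``base`` is a Gompertz-like log-rate schedule at the window midpoint
and ``slope`` the annual change of the log rate.  Optional multiplicative
shocks create pandemic-like departures from trend in chosen years.

Default schedules are calibrated to a low-mortality European setting: life
expectancies at birth of roughly 81 years for men and 85 for women, log
rates declining by 2%/yr (men) and 1%/yr (women), and 0.75%/yr population
growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .panel import PANEL_COLUMNS, class_labels, check_class_edges, validate_panel
from .standardize import WeeklyDeathTable

#: Gompertz log-rate parameters (a, b): log m(i) = a + b*i at the window
#: midpoint, calibrated so the implied life expectancy at birth is ~81 (men)
#: and ~85 (women)
DEFAULT_GOMPERTZ = {"male": (-10.576, 0.095), "female": (-11.328, 0.10)}
DEFAULT_SLOPE = {"male": -0.02, "female": -0.01}
#: annual relative population growth
DEFAULT_POP_GROWTH = 0.0075
#: weekly reporting classes: 0-19, 20-39, 40-64, 65-79, 80+
WEEKLY_CLASS_EDGES = (0, 20, 40, 65, 80)


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


def _default_pop0(ages: np.ndarray) -> np.ndarray:
    """Smooth population pyramid: ~60k per young age, thinning above ~70."""
    return 60_000.0 * np.exp(-((ages / 70.0) ** 4))


def _resolve(spec, ages: np.ndarray, *, name: str) -> np.ndarray:
    """Resolve a per-age specification: scalar, (a, b) affine pair, array of
    len(ages), or callable on the age vector."""
    if callable(spec):
        return np.asarray(spec(ages), dtype=float)
    if np.isscalar(spec):
        return np.full(ages.shape, float(spec))
    arr = np.asarray(spec, dtype=float)
    if arr.shape == (2,) and name in ("baseline_log_rate",):
        a, b = arr
        return a + b * ages
    if arr.shape != ages.shape:
        raise ConfigurationError(
            f"{name}: expected scalar, callable or array of length {ages.size}")
    return arr


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic mortality panel.

    ``baseline_log_rate`` and ``slope`` map each sex to a per-age
    specification (scalar, (intercept, slope-in-age) pair for the baseline,
    per-age array, or callable).  ``shock`` maps years to per-age
    multiplicative factors on the rates.  All randomness is governed by
    ``seed``.
    """

    years: tuple[int, int] = (2010, 2022)
    open_age: int = 100
    sexes: tuple = ("male", "female")
    baseline_log_rate: Mapping = field(default_factory=lambda: dict(DEFAULT_GOMPERTZ))
    slope: Mapping = field(default_factory=lambda: dict(DEFAULT_SLOPE))
    pop0: Mapping | Callable | float | None = None
    pop_growth: float = DEFAULT_POP_GROWTH
    shock: Mapping[int, object] | None = None
    seed: int = 0

    @property
    def ages(self) -> np.ndarray:
        return np.arange(0, self.open_age + 1)

    @property
    def year_midpoint(self) -> float:
        return (self.years[0] + self.years[1]) / 2.0

    def validate(self) -> "SimulationConfig":
        if self.years[1] <= self.years[0]:
            raise ConfigurationError("years must span at least two values")
        if self.open_age < 1:
            raise ConfigurationError("open_age must be positive")
        ages = self.ages
        for sex in self.sexes:
            if sex not in self.baseline_log_rate or sex not in self.slope:
                raise ConfigurationError(f"missing baseline or slope for sex {sex!r}")
            rates = np.exp(_resolve(self.baseline_log_rate[sex], ages,
                                    name="baseline_log_rate"))
            if np.any(rates <= 0) or np.any(rates > 1):
                raise ConfigurationError(
                    f"baseline rates for {sex!r} must lie in (0, 1]")
            if np.any(self._pop0_for(sex) <= 0):
                raise ConfigurationError("initial populations must be positive")
        if self.shock is not None:
            for year, factors in self.shock.items():
                if not (self.years[0] <= year <= self.years[1]):
                    raise ConfigurationError(f"shock year {year} outside simulation years")
                if np.any(_resolve(factors, ages, name="shock") <= 0):
                    raise ConfigurationError("shock factors must be positive")
        return self

    def _pop0_for(self, sex) -> np.ndarray:
        ages = self.ages
        if self.pop0 is None:
            return _default_pop0(ages)
        spec = self.pop0[sex] if isinstance(self.pop0, Mapping) else self.pop0
        return _resolve(spec, ages, name="pop0")

    def true_rate(self, sex, year: int) -> np.ndarray:
        """The deterministic rate surface at one (sex, year)."""
        ages = self.ages
        log_m = (_resolve(self.baseline_log_rate[sex], ages, name="baseline_log_rate")
                 + _resolve(self.slope[sex], ages, name="slope")
                 * (year - self.year_midpoint))
        m = np.exp(log_m)
        if self.shock and year in self.shock:
            m = m * _resolve(self.shock[year], ages, name="shock")
        return m

    def population(self, sex, year: int) -> np.ndarray:
        p = self._pop0_for(sex) * (1.0 + self.pop_growth) ** (year - self.years[0])
        return np.maximum(np.rint(p), 1.0).astype(int)


def generate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Draw a full mortality panel: Poisson deaths around the rate surface.

    Deterministic given ``config.seed``; deaths are clipped at the
    population size (the clip binds only in pathological configurations).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    years = np.arange(config.years[0], config.years[1] + 1)
    frames = []
    for sex in config.sexes:
        for year in years:
            pop = config.population(sex, year)
            mu = pop * config.true_rate(sex, int(year))
            deaths = np.minimum(rng.poisson(mu), pop)
            frames.append(pd.DataFrame({
                "sex": sex, "age": config.ages, "year": int(year),
                "deaths": deaths.astype(float), "population": pop,
            }))
    return validate_panel(pd.concat(frames, ignore_index=True)[PANEL_COLUMNS])


def apply_shock(panel: pd.DataFrame, year: int, factors, seed: int) -> pd.DataFrame:
    """Re-draw one year's deaths as Poisson(P * m * factor), m the empirical
    rate; other years are untouched.  Creates a pandemic-like departure in
    an already-generated panel."""
    if year not in set(panel["year"]):
        raise KeyError(f"year {year} not present in panel")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    for sex in out["sex"].unique():
        mask = (out["sex"] == sex) & (out["year"] == year)
        sub = out.loc[mask].sort_values("age")
        ages = sub["age"].to_numpy()
        f = _resolve(factors, ages, name="shock")
        if np.any(f < 0):
            raise ConfigurationError("shock factors must be non-negative")
        pop = sub["population"].to_numpy(dtype=float)
        mu = sub["deaths"].to_numpy(dtype=float) * f
        out.loc[sub.index, "deaths"] = np.minimum(rng.poisson(mu), pop).astype(float)
    return out


def generate_weekly(panel: pd.DataFrame, year: int, n_weeks: int = 52,
                    seasonal_amplitude: float = 0.0, wave_spec=None,
                    seed: int = 0, class_edges=WEEKLY_CLASS_EDGES,
                    peak_week: int = 2) -> WeeklyDeathTable:
    """Split one year's deaths multinomially over weeks, by coarse age class.

    Week weights are proportional to ``1 + amplitude * cos(2*pi*(w -
    peak_week)/n_weeks)`` (a winter mortality peak) plus optional Gaussian
    pulses from ``wave_spec`` — a sequence of ``(center_week, width_weeks,
    height)`` triples emulating epidemic or heat waves.  Weekly counts sum
    exactly to the annual class totals; populations for every panel year are
    attached so standardized weekly deaths can be computed downstream.
    """
    if not 0 <= seasonal_amplitude < 1:
        raise ConfigurationError("seasonal_amplitude must lie in [0, 1)")
    if n_weeks not in (52, 53):
        raise ConfigurationError("n_weeks must be 52 or 53")
    if year not in set(panel["year"]):
        raise KeyError(f"year {year} not present in panel")
    edges = check_class_edges(class_edges)
    labels = class_labels(edges)
    rng = np.random.default_rng(seed)

    weeks = np.arange(1, n_weeks + 1)
    weights = 1.0 + seasonal_amplitude * np.cos(2 * np.pi * (weeks - peak_week) / n_weeks)
    if wave_spec:
        for center, width, height in wave_spec:
            weights = weights + height * np.exp(-0.5 * ((weeks - center) / width) ** 2)
    if np.any(weights <= 0):
        raise ConfigurationError("week weights must be positive")
    probs = weights / weights.sum()

    idx = np.searchsorted(edges, panel["age"].to_numpy(), side="right") - 1
    tmp = panel.assign(age_class=np.asarray(labels)[idx])
    deaths_rows = []
    annual = (tmp[tmp["year"] == year]
              .groupby("age_class", sort=False)["deaths"].sum())
    for k in labels:
        total = int(round(annual.get(k, 0.0)))
        counts = rng.multinomial(total, probs)
        deaths_rows.append(pd.DataFrame({
            "year": year, "week": weeks, "age_class": k, "deaths": counts}))
    pops = (tmp.groupby(["year", "age_class"], sort=False, as_index=False)
               ["population"].sum())
    return WeeklyDeathTable(deaths=pd.concat(deaths_rows, ignore_index=True),
                            populations=pops)
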