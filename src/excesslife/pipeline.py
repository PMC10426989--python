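"""End-to-end dual-approach analysis.

Orchestrates the full comparison of a pandemic-era year's mortality against
(1) a pre-pandemic level year and (2) the extrapolated pre-pandemic trend:
calendar corrections, standardized rates for every year, the per-sex
Poisson trend fit, excess mortality/deaths under both comparators (overall
and by age class), life expectancy at birth and at 50 (observed and
predicted), and the per-sex summary report.  Fully deterministic given its
inputs; the only randomness in the package lives in the synthetic-data
generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import lifetable
from .excess import Z_95, excess_by_age_class, excess_vs_reference, excess_vs_trend
from .io import read_panel_csv, read_weekly_csv, write_panel_csv, write_results
from .panel import aggregate_ages, class_labels, panel_years, subset
from .simulate import SimulationConfig, generate_panel
from .standardize import (WeeklyDeathTable, leap_adjust, standardized_rate,
                          swd_series, weekly_to_annual)
from .trend import PoissonTrendModel

logger = logging.getLogger("excesslife")

#: leap years within the default study period
DEFAULT_LEAP_YEARS = (2012, 2016, 2020)
#: 10-year reporting classes with open class 90+
DEFAULT_CLASS_EDGES = tuple(range(0, 100, 10))


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    Either CSV paths (``deaths_path`` and, if deaths and populations live in
    separate files, ``population_path``) or a :class:`SimulationConfig` must
    be supplied.  ``ref_year`` is the standardization reference (its January-1
    population provides weights and scale); ``level_year`` the pre-pandemic
    comparison level; ``trend_years`` the years compared against the trend.
    """

    deaths_path: str | None = None
    population_path: str | None = None
    weekly_deaths_path: str | None = None
    weekly_population_path: str | None = None
    simulation: SimulationConfig | None = None
    ref_year: int = 2022
    level_year: int = 2019
    comparison_years: tuple = (2020, 2021, 2022)
    trend_years: tuple = (2022,)
    fit_window: tuple = (2010, 2019)
    class_edges: tuple = DEFAULT_CLASS_EDGES
    leap_years: tuple = DEFAULT_LEAP_YEARS
    z_multiplier: float = Z_95
    out_dir: str = "excesslife-output"
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if self.simulation is None and self.deaths_path is None:
            raise ValueError("either input CSV paths or a simulation config is required")
        if self.fit_window[1] >= min(self.comparison_years):
            raise ValueError("trend fit window must precede the comparison years")
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            sim = {k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            if "seed" not in sim:
                sim["seed"] = cfg.seed
            cfg.simulation = SimulationConfig(**sim)
        return cfg.validate()


def load_panel(config: AnalysisConfig) -> pd.DataFrame:
    """Load or simulate the panel; fold in any weekly-only year first, so
    the week-boundary correction precedes the leap-year correction."""
    if config.simulation is not None:
        logger.info("generating synthetic panel (seed=%d)", config.simulation.seed)
        panel = generate_panel(config.simulation)
    else:
        panel = read_panel_csv(config.deaths_path, config.population_path)
    if config.weekly_deaths_path is not None:
        weekly = read_weekly_csv(config.weekly_deaths_path,
                                 config.weekly_population_path)
        for year in sorted(weekly.deaths["year"].unique()):
            panel = attach_weekly_year(panel, weekly, int(year))
    return panel


def _comparison_rows(panel, sex, config, fit):
    """The summary rows: each comparison year vs the level year, then the
    trend years vs their predictions."""
    rows = []
    e_level = {start: lifetable.life_expectancy(
        lifetable.class_rates(panel, sex, config.level_year), sex=sex,
        year=config.level_year, start_age=start) for start in (0, 50)}
    rate_level = standardized_rate(panel, sex, config.level_year, config.ref_year)
    ref_pop = float(subset(panel, sex=sex, year=config.ref_year)["population"].sum())
    for year in config.comparison_years:
        rate_y = standardized_rate(panel, sex, year, config.ref_year)
        est = excess_vs_reference(rate_y, rate_level, ref_pop, z=config.z_multiplier)
        e_y = {start: lifetable.life_expectancy(
            lifetable.class_rates(panel, sex, year), sex=sex, year=year,
            start_age=start) for start in (0, 50)}
        rows.append({
            "comparison": f"{year} vs {config.level_year}", "excess": est,
            "lel_months": lifetable.life_expectancy_loss(e_y[0], e_level[0]),
            "lel50_months": lifetable.life_expectancy_loss(e_y[50], e_level[50])})
    for year in config.trend_years:
        rate_y = standardized_rate(panel, sex, year, config.ref_year)
        rate_hat = fit.predict_standardized_rate(year, panel, config.ref_year)
        est = excess_vs_trend(rate_y, rate_hat, ref_pop, z=config.z_multiplier)
        e_obs = {start: lifetable.life_expectancy(
            lifetable.class_rates(panel, sex, year), sex=sex, year=year,
            start_age=start) for start in (0, 50)}
        mu_hat = lifetable.predicted_class_rates(fit, panel, sex, year)
        e_hat = {start: lifetable.life_expectancy(
            mu_hat, sex=sex, year=year, start_age=start, source="predicted")
            for start in (0, 50)}
        rows.append({
            "comparison": f"{year} vs trend", "excess": est,
            "lel_months": lifetable.life_expectancy_loss(e_obs[0], e_hat[0]),
            "lel50_months": lifetable.life_expectancy_loss(e_obs[50], e_hat[50])})
    return rows


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and write the report files.

    Returns a dict with the corrected panel, per-sex trend fits, summary
    rows, stratified estimates, life-expectancy series and output paths.
    """
    config.validate()
    panel = load_panel(config)
    panel = leap_adjust(panel, set(config.leap_years) & set(panel_years(panel)))
    logger.info("panel: %d records, years %s", len(panel), panel_years(panel))

    sexes = list(panel["sex"].unique())
    results, fits, by_class, le_series = {}, {}, {}, {}
    for sex in sexes:
        fit = PoissonTrendModel(sex=sex, fit_window=config.fit_window).fit(panel)
        fits[sex] = fit
        results[sex] = _comparison_rows(panel, sex, config, fit)
        strat = []
        for year in config.trend_years:
            strat += excess_by_age_class(panel, sex, year, config.level_year,
                                         config.class_edges, config.ref_year,
                                         z=config.z_multiplier)
            strat += excess_by_age_class(panel, sex, year, fit,
                                         config.class_edges, config.ref_year,
                                         z=config.z_multiplier)
        by_class[sex] = strat
        le_rows = []
        for year in panel_years(panel):
            e_obs = lifetable.life_expectancy(
                lifetable.class_rates(panel, sex, year), sex=sex, year=year)
            e_hat = lifetable.life_expectancy(
                lifetable.predicted_class_rates(fit, panel, sex, year),
                sex=sex, year=year, source="predicted")
            le_rows.append({"year": year, "le_observed": e_obs.expectancy,
                            "le_predicted": e_hat.expectancy})
        le_series[sex] = pd.DataFrame(le_rows)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_results(results, out_dir)
    for sex in sexes:
        le_series[sex].to_csv(out_dir / f"life_expectancy_{sex}.csv", index=False)
        rows = [{"comparator": e.comparator, "age_low": e.age_range[0],
                 "age_high": e.age_range[1], "em_percent": e.em_percent,
                 "ci_low": e.ci_low, "ci_high": e.ci_high,
                 "excess_deaths": e.excess_deaths, "significant": e.significant}
                for e in by_class[sex]]
        pd.DataFrame(rows).to_csv(out_dir / f"excess_by_class_{sex}.csv", index=False)
    write_panel_csv(panel, out_dir / "panel_corrected.csv")
    logger.info("report written to %s", out_dir)
    return {"panel": panel, "fits": fits, "results": results,
            "by_class": by_class, "le_series": le_series, "paths": paths}


def attach_weekly_year(panel: pd.DataFrame, weekly: WeeklyDeathTable, year: int,
                       lead_fraction: float = 2.0 / 7.0,
                       tail_fraction: float = 1.0 / 7.0) -> pd.DataFrame:
    """Fold a weekly-only final year into an annual panel at class resolution.

    The weekly table's classes define the common age resolution: the annual
    panel is aggregated to those classes, and the new year's deaths are the
    week sums with the lead/tail boundary corrections.  Weekly sources carry
    no sex split, so each class's deaths are apportioned between sexes by
    the class population shares of ``year``.
    """
    from .io import parse_age

    labels = weekly.classes()
    edges = sorted(parse_age(lab) for lab in labels)
    agg = aggregate_ages(panel, edges)
    annual = weekly_to_annual(weekly, year, lead_fraction, tail_fraction)
    label_for_edge = dict(zip(sorted(edges), class_labels(edges)))
    pops = weekly.populations
    rows = []
    for sex in agg["sex"].unique():
        ref = subset(panel, sex=sex, year=year)
        if ref.empty:
            raise KeyError(f"populations for year {year} missing from panel")
        ref = aggregate_ages(ref, edges).set_index("age")
        both = (aggregate_ages(subset(panel, year=year), edges)
                .groupby("age")["population"].sum())
        for edge in edges:
            share = ref.loc[edge, "population"] / both.loc[edge]
            rows.append({"sex": sex, "age": edge, "year": year,
                         "deaths": float(annual[label_for_edge[edge]]) * share,
                         "population": int(ref.loc[edge, "population"])})
    agg = agg[agg["year"] != year]
    return pd.concat([agg, pd.DataFrame(rows)], ignore_index=True)


def swd_report(weekly: WeeklyDeathTable, ref_year: int) -> pd.DataFrame:
    """Standardized weekly death series for plotting or export."""
    return swd_series(weekly, ref_year)
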