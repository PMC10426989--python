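"""Reading and writing the tabular formats.

Input CSVs are long-format tables in the style of statistical-office
exports: comma separated, UTF-8, mandatory header, "." decimal separator.
Numeric fields may carry apostrophes or narrow spaces as thousands
separators (e.g. "8'738'791"); the parser strips them.  Open age classes
are written "100+" and parsed to their lower bound; a ``week`` column marks
a weekly death table rather than an annual panel.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .panel import PANEL_COLUMNS, PanelSchemaError, validate_panel
from .report import round_half_away
from .standardize import WeeklyDeathTable

_THOUSANDS = re.compile("[\u2019'\u202f\u2009 ]")


def _clean_numeric(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        series = series.astype(str).str.replace(_THOUSANDS, "", regex=True)
    return pd.to_numeric(series)


def parse_age(value) -> int:
    """Parse an age field: plain integers, open classes "100+", and class
    labels "90-94" (mapped to the lower bound)."""
    s = str(value).strip()
    if s.endswith("+"):
        return int(s[:-1])
    if "-" in s and not s.lstrip().startswith("-"):
        return int(s.split("-")[0])
    return int(float(s))


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_panel_csv(path, population_path=None):
    """Read a mortality panel (or weekly table; see below) from CSV.

    One file holding sex, age, year, deaths, population is read directly;
    alternatively a deaths file plus a ``population_path`` file are merged
    on (sex, age, year).  A ``week`` column switches to weekly parsing and
    returns a :class:`WeeklyDeathTable` (``population_path`` then supplies
    the per-class populations).
    """
    df = read_table(path)
    if "week" in df.columns:
        if population_path is None:
            raise PanelSchemaError("weekly deaths need a companion population file")
        return read_weekly_csv(path, population_path)
    if "age" not in df.columns:
        if "age_class" in df.columns:
            df = df.rename(columns={"age_class": "age"})
        else:
            raise PanelSchemaError("panel is missing column(s): age")
    df["age"] = df["age"].map(parse_age)
    if population_path is not None:
        pop = read_table(population_path)
        if "age" not in pop.columns and "age_class" in pop.columns:
            pop = pop.rename(columns={"age_class": "age"})
        pop["age"] = pop["age"].map(parse_age)
        pop["population"] = _clean_numeric(pop["population"])
        df = df.merge(pop[["sex", "age", "year", "population"]],
                      on=["sex", "age", "year"], how="left")
        if df["population"].isna().any():
            raise PanelSchemaError("population missing for some (sex, age, year)")
    for col in ("deaths", "population"):
        if col not in df.columns:
            raise PanelSchemaError(f"panel is missing column(s): {col}")
        df[col] = _clean_numeric(df[col])
    df["year"] = _clean_numeric(df["year"]).astype(int)
    return validate_panel(df)


def read_weekly_csv(deaths_path, population_path) -> WeeklyDeathTable:
    deaths = read_table(deaths_path)
    pops = read_table(population_path)
    for col in ("year", "week", "age_class", "deaths"):
        if col not in deaths.columns:
            raise PanelSchemaError(f"weekly deaths table missing column {col!r}")
    deaths["deaths"] = _clean_numeric(deaths["deaths"])
    pops["population"] = _clean_numeric(pops["population"])
    return WeeklyDeathTable(deaths=deaths, populations=pops)


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def write_weekly_csv(weekly: WeeklyDeathTable, deaths_path, population_path) -> None:
    weekly.deaths.to_csv(deaths_path, index=False)
    weekly.populations.to_csv(population_path, index=False)


REPORT_COLUMNS = ["comparison", "em_percent", "ci_low", "ci_high",
                  "excess_deaths", "lel_months", "lel50_months"]


def write_results(results: dict, out_dir) -> dict[str, Path]:
    """Write the per-sex summary report.

    ``results`` maps each sex to a list of comparison rows, each a dict with
    keys ``comparison`` (e.g. "2022 vs 2019", "2022 vs trend"), ``excess``
    (an ExcessEstimate) and ``lel_months`` / ``lel50_months``.  Two files
    are produced per sex: a rounded table at reporting precision (EM/CI one
    decimal, deaths integer, losses one decimal) and an unrounded
    machine-readable copy.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for sex, rows in results.items():
        raw, rounded = [], []
        for row in rows:
            est = row["excess"]
            rec = {"comparison": row["comparison"], "em_percent": est.em_percent,
                   "ci_low": est.ci_low, "ci_high": est.ci_high,
                   "excess_deaths": est.excess_deaths,
                   "lel_months": row["lel_months"],
                   "lel50_months": row["lel50_months"]}
            raw.append(rec)
            rounded.append({"comparison": rec["comparison"],
                            "em_percent": round_half_away(rec["em_percent"], 1),
                            "ci_low": round_half_away(rec["ci_low"], 1),
                            "ci_high": round_half_away(rec["ci_high"], 1),
                            "excess_deaths": round_half_away(rec["excess_deaths"], 0),
                            "lel_months": round_half_away(rec["lel_months"], 1),
                            "lel50_months": round_half_away(rec["lel50_months"], 1)})
        for suffix, data in (("", rounded), ("_unrounded", raw)):
            path = out_dir / f"report_{sex}{suffix}.csv"
            pd.DataFrame(data, columns=REPORT_COLUMNS).to_csv(path, index=False)
            written[f"{sex}{suffix}"] = path
    return written
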