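"""Mortality panel container and age-class utilities.

A *mortality panel* is the Lexis-style long table underlying every
computation in this package: one row per (sex, age, year) holding the
number of deaths during the calendar year and the population size on
January 1.  It is represented as a plain :class:`pandas.DataFrame` with
columns ``sex``, ``age``, ``year``, ``deaths``, ``population``; the top
age is an open class (e.g. 100 means "100 and over").  Deaths are real
valued because calendar corrections (leap-year exclusion, week-boundary
alignment) produce fractional counts.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["sex", "age", "year", "deaths", "population"]


class PanelSchemaError(ValueError):
    """The input table does not satisfy the panel contract."""


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a mortality panel and return it with canonical column order.

    Checks: required columns present, one record per (sex, age, year),
    ages contiguous from 0 to the open class within each (sex, year),
    deaths non-negative, population >= 1.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelSchemaError(f"panel is missing column(s): {', '.join(missing)}")
    out = panel[PANEL_COLUMNS].copy()
    if out.duplicated(subset=["sex", "age", "year"]).any():
        raise PanelSchemaError("duplicate (sex, age, year) records in panel")
    if (out["deaths"] < 0).any():
        raise PanelSchemaError("negative death counts in panel")
    if (out["population"] < 1).any():
        raise PanelSchemaError("population sizes must be >= 1")
    for (sex, year), grp in out.groupby(["sex", "year"]):
        ages = np.sort(grp["age"].to_numpy())
        # class-aggregated panels carry lower bounds, so contiguity is not
        # enforceable in general, but every panel must start at age 0
        if ages[0] != 0:
            raise PanelSchemaError(
                f"ages for sex={sex}, year={year} do not start at 0")
    return out


def panel_years(panel: pd.DataFrame) -> list[int]:
    return sorted(int(y) for y in panel["year"].unique())


def panel_ages(panel: pd.DataFrame, sex=None) -> np.ndarray:
    sub = panel if sex is None else panel[panel["sex"] == sex]
    return np.sort(sub["age"].unique())


def subset(panel: pd.DataFrame, sex=None, year: int | None = None,
           age_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Restrict a panel to a sex, a year and/or a half-open age interval."""
    mask = pd.Series(True, index=panel.index)
    if sex is not None:
        mask &= panel["sex"] == sex
    if year is not None:
        mask &= panel["year"] == year
    if age_range is not None:
        lo, hi = age_range
        mask &= (panel["age"] >= lo) & (panel["age"] < hi)
    return panel[mask]


def class_labels(edges: Sequence[float]) -> list[str]:
    """Human-readable labels for half-open classes, last one open ("90+")."""
    labels = [f"{int(a)}-{int(b) - 1}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f"{int(edges[-1])}+")
    return labels


def check_class_edges(edges: Sequence[float]) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.size == 0 or edges[0] != 0:
        raise ValueError("age-class edges must start at 0")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("age-class edges must be strictly increasing")
    return edges


def aggregate_ages(panel: pd.DataFrame, class_edges: Iterable[float]) -> pd.DataFrame:
    """Collapse single ages into half-open classes [a, b), last class open.

    The returned panel uses each class's lower bound as its ``age``, so all
    rate operations accept it unchanged.  Deaths and populations are summed
    within classes; totals are preserved for any partition.
    """
    edges = check_class_edges(list(class_edges))
    out = panel.copy()
    idx = np.searchsorted(edges, out["age"].to_numpy(), side="right") - 1
    out["age"] = edges[idx].astype(int)
    agg = (out.groupby(["sex", "age", "year"], as_index=False)[["deaths", "population"]]
              .sum())
    return agg[PANEL_COLUMNS]
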