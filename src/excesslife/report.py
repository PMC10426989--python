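"""Report formatting: rounding rules and summary ratios.

Reporting precision follows the conventions of national mortality reports:
excess mortality and its CI to one decimal in %, excess deaths to whole
counts, life expectancy losses to one decimal in months.  Rounding is
half-away-from-zero (so 2.55 -> 2.6 and -2.55 -> -2.6), not banker's
rounding.
"""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals."""
    if math.isnan(x):
        return x
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def trend_to_level_ratio(trend_value: float, level_value: float,
                         ndigits: int = 1) -> float:
    """How many times larger a trend-based excess figure is than the
    level-based one (e.g. excess deaths vs trend / excess deaths vs 2019),
    rounded at reporting precision."""
    if level_value == 0:
        raise ZeroDivisionError("level-based figure is zero")
    return round_half_away(trend_value / level_value, ndigits)


def annual_growth_rates(populations) -> list[float]:
    """Year-over-year relative growth of a population series, in percent."""
    pops = list(populations)
    if len(pops) < 2:
        raise ValueError("need at least two population sizes")
    return [100.0 * (b / a - 1.0) for a, b in zip(pops[:-1], pops[1:])]
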