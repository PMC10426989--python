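"""Excess mortality and excess deaths: CI formulas, conservation, power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from excesslife import (SimulationConfig, excess_by_age_class, excess_vs_reference,
                        excess_vs_trend, fit_trend, generate_panel,
                        standardized_rate)
from excesslife.standardize import DegenerateRateError, StandardizedRate

from conftest import make_panel


def rate(value, var_log, year=2022, source="observed", **kw):
    kw.setdefault("sex", "m")
    kw.setdefault("ref_year", 2022)
    return StandardizedRate(value=value, var_log=var_log, year=year,
                            source=source, **kw)


class TestVsReference:
    def test_identity(self):
        est = excess_vs_reference(rate(0.01, 1e-4), rate(0.01, 1e-4, year=2019),
                                  ref_pop_total=1e6)
        assert est.em_percent == 0.0
        assert est.excess_deaths == 0.0
        assert est.ci_low < 0 < est.ci_high

    def test_hand_ci_single_stratum(self):
        """D_y=121 vs D_z=100, equal populations: the printed CI formula."""
        est = excess_vs_reference(rate(121 / 1e5, 1 / 121),
                                  rate(100 / 1e5, 1 / 100, year=2019), 1e5)
        half = 1.96 * math.sqrt(1 / 121 + 1 / 100)
        assert est.em_percent == pytest.approx(21.0, abs=1e-10)
        assert est.ci_low == pytest.approx(100 * math.exp(math.log(1.21) - half) - 100,
                                           abs=1e-10)
        assert est.ci_high == pytest.approx(100 * math.exp(math.log(1.21) + half) - 100,
                                            abs=1e-10)
        # magnitude sanity against the rounded hand evaluation
        assert est.ci_low == pytest.approx(-7.2, abs=0.05)
        assert est.ci_high == pytest.approx(57.7, abs=0.05)

    def test_excess_deaths_scale(self):
        est = excess_vs_reference(rate(0.022, 1e-5), rate(0.020, 1e-5, year=2019), 1e6)
        assert est.excess_deaths == pytest.approx(2000.0, abs=1e-9)

    def test_degenerate_comparator_raises(self):
        with pytest.raises(DegenerateRateError):
            excess_vs_reference(rate(0.01, 1e-4),
                                rate(0.0, float("nan"), year=2019), 1e6)

    def test_source_and_alignment_checks(self):
        with pytest.raises(ValueError):
            excess_vs_reference(rate(0.01, 1e-4),
                                rate(0.01, 1e-4, year=2019, source="predicted"), 1e6)
        with pytest.raises(ValueError):
            excess_vs_reference(rate(0.01, 1e-4),
                                rate(0.01, 1e-4, year=2019, sex="f"), 1e6)


class TestVsTrend:
    def test_zero_model_variance_reduces_to_poisson_term(self):
        obs = rate(0.01, 1 / 400)
        hat = rate(0.01, 0.0, source="predicted")
        est = excess_vs_trend(obs, hat, 1e6)
        assert est.em_percent == 0.0
        half = 1.96 * math.sqrt(1 / 400)
        assert est.ci_high == pytest.approx(100 * math.exp(half) - 100, abs=1e-10)

    def test_wider_interval_with_model_variance(self):
        obs = rate(0.011, 1 / 500)
        narrow = excess_vs_trend(obs, rate(0.01, 1e-5, source="predicted"), 1e6)
        wide = excess_vs_trend(obs, rate(0.01, 5e-4, source="predicted"), 1e6)
        assert (wide.ci_high - wide.ci_low) > (narrow.ci_high - narrow.ci_low)

    def test_known_shock_recovered(self):
        """+8% uniform rate shock against an exactly known trend: the mean EM
        over replicates sits at 8%."""
        rng = np.random.default_rng(17)
        pops = np.array([80_000, 40_000])
        rates = np.array([0.005, 0.02])
        n_rep, ems = 500, []
        for _ in range(n_rep):
            d = rng.poisson(pops * rates * 1.08)
            panel = make_panel([("m", a, 2022, float(d[a]), int(pops[a]))
                                for a in range(2)])
            obs = standardized_rate(panel, "m", 2022, ref_year=2022)
            truth = rate(float((pops * rates).sum() / pops.sum()), 0.0,
                         source="predicted")
            ems.append(excess_vs_trend(obs, truth, pops.sum()).em_percent)
        se = np.std(ems, ddof=1) / math.sqrt(n_rep)
        assert np.mean(ems) == pytest.approx(8.0, abs=4 * se)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(min_value=1, max_value=10_000),
       st.integers(min_value=1, max_value=10_000))
def test_ci_symmetric_on_log_scale(dy, dz):
    """log-midpoint of the (1 + ci/100) endpoints equals log(1 + em/100)."""
    est = excess_vs_reference(rate(dy / 1e6, 1 / dy), rate(dz / 1e6, 1 / dz, year=2019),
                              1e6)
    mid = 0.5 * (math.log1p(est.ci_low / 100) + math.log1p(est.ci_high / 100))
    assert mid == pytest.approx(math.log1p(est.em_percent / 100), abs=1e-10)


def test_delta_ci_close_to_bootstrap_percentile():
    """Percentile bootstrap CI within 2 percentage points of the delta CI
    on a small panel with >=500 deaths per year."""
    rng = np.random.default_rng(3)
    d_y, d_z = np.array([300.0, 280.0]), np.array([260.0, 250.0])
    pops = np.array([40_000, 25_000])
    panel = make_panel(
        [("m", a, 2019, d_z[a], int(pops[a])) for a in range(2)]
        + [("m", a, 2022, d_y[a], int(pops[a])) for a in range(2)])
    obs_y = standardized_rate(panel, "m", 2022, ref_year=2022)
    obs_z = standardized_rate(panel, "m", 2019, ref_year=2022)
    delta = excess_vs_reference(obs_y, obs_z, pops.sum())
    boot = []
    for _ in range(4000):
        ry = (rng.poisson(d_y) * 1.0).sum() / pops.sum()
        rz = (rng.poisson(d_z) * 1.0).sum() / pops.sum()
        if rz > 0:
            boot.append(100 * ry / rz - 100)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    assert delta.ci_low == pytest.approx(lo, abs=2.0)
    assert delta.ci_high == pytest.approx(hi, abs=2.0)


class TestByAgeClass:
    def test_single_class_equals_all_ages(self, default_panel):
        whole = excess_by_age_class(default_panel, "male", 2022, 2019, [0], 2022)
        assert len(whole) == 1
        obs = standardized_rate(default_panel, "male", 2022, ref_year=2022)
        ref = standardized_rate(default_panel, "male", 2019, ref_year=2022)
        pop = default_panel[(default_panel["sex"] == "male")
                            & (default_panel["year"] == 2022)]["population"].sum()
        direct = excess_vs_reference(obs, ref, pop)
        assert whole[0].em_percent == pytest.approx(direct.em_percent, rel=1e-12)
        assert whole[0].excess_deaths == pytest.approx(direct.excess_deaths, rel=1e-12)

    def test_class_excess_deaths_sum_to_total(self, default_panel):
        edges = list(range(0, 100, 10))
        per_class = excess_by_age_class(default_panel, "female", 2022, 2019,
                                        edges, 2022)
        whole = excess_by_age_class(default_panel, "female", 2022, 2019, [0], 2022)
        assert sum(e.excess_deaths for e in per_class) == pytest.approx(
            whole[0].excess_deaths, rel=1e-9)
        fit = fit_trend(default_panel, "female", (2010, 2019))
        per_class_t = excess_by_age_class(default_panel, "female", 2022, fit,
                                          edges, 2022)
        whole_t = excess_by_age_class(default_panel, "female", 2022, fit, [0], 2022)
        assert sum(e.excess_deaths for e in per_class_t) == pytest.approx(
            whole_t[0].excess_deaths, rel=1e-9)

    def test_shock_detected_only_in_old_classes(self):
        """A rate shock at 80+ produces significant excess in the 80+ class
        and not (systematically) elsewhere."""
        detected_old, detected_young = 0, 0
        n_seeds = 25
        for s in range(n_seeds):
            cfg = SimulationConfig(
                years=(2018, 2022), sexes=("male",),
                slope={"male": 0.0},
                shock={2022: lambda ages: np.where(ages >= 80, 1.3, 1.0)},
                seed=s)
            panel = generate_panel(cfg)
            ests = excess_by_age_class(panel, "male", 2022, 2019,
                                       list(range(0, 100, 10)), 2022)
            for e in ests:
                if e.age_range[0] >= 80 and e.significant and e.em_percent > 0:
                    detected_old += 1
                if e.age_range[0] < 60 and e.significant:
                    detected_young += 1
        assert detected_old >= 0.9 * 2 * n_seeds        # both 80-89 and 90+
        assert detected_young <= 0.25 * 6 * n_seeds     # ~5% false positive rate
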