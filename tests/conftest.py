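import numpy as np
import pandas as pd
import pytest

from excesslife import SimulationConfig, generate_panel
from excesslife.panel import validate_panel


def make_panel(records):
    """Build a validated panel from (sex, age, year, deaths, population) rows."""
    return validate_panel(pd.DataFrame(
        records, columns=["sex", "age", "year", "deaths", "population"]))


@pytest.fixture
def two_stratum_panel():
    """Two ages, one sex, two years; the worked example used across modules."""
    return make_panel([
        ("m", 0, 2021, 10.0, 1000), ("m", 1, 2021, 20.0, 500),
        ("m", 0, 2022, 12.0, 600), ("m", 1, 2022, 25.0, 400),
    ])


@pytest.fixture(scope="session")
def default_panel():
    """A full synthetic panel under the default study conditions."""
    return generate_panel(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def small_config():
    """A reduced-age configuration for fits that must be cheap."""
    return SimulationConfig(
        years=(2010, 2022), open_age=30, sexes=("male",),
        baseline_log_rate={"male": (-7.5, 0.05)},
        slope={"male": -0.015}, pop0=200_000.0, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


def poisson_se_band(mean, n_rep, k=4.0):
    """Half-width of a k-sigma Monte-Carlo band for a Poisson mean."""
    return k * np.sqrt(mean / n_rep)
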