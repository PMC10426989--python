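"""Pre-pandemic mortality trend: a Poisson log-linear model per sex.

For each sex the expected death count at age ``i`` in year ``y`` is modelled
as

    E[D_iy] = P_iy * exp(alpha_i + beta_i * (y - c)),

i.e. a Poisson generalized linear model with log link, age as a categorical
factor, a linear year covariate with a full age x year interaction, and the
log population as offset.  Because every age has its own intercept and
slope, the joint model decomposes exactly into independent two-parameter
fits per age; this module fits them by Newton's method on the Poisson
log-likelihood (equivalently, iteratively reweighted least squares), giving
maximum-likelihood coefficients and their covariance from the observed
information.

Fitted models extrapolate the declining trend into pandemic years: they
produce predicted age-specific rates, their log-scale variances

    V[log m_i(y)] = Var(alpha_i) + (y-c)^2 Var(beta_i) + 2 (y-c) Cov,

and predicted standardized rates with delta-method variances

    V[log m^(y,s)] = (1/m^2) * sum_i (m_i P_i^s / P^s)^2 V[log m_i(y)].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import PanelSchemaError, subset
from .standardize import StandardizedRate

_MAX_ITER = 100
_REL_TOL = 1e-10


class SparseDataError(ValueError):
    """An age has no deaths over the fit window; aggregate ages first."""


def _fit_poisson_loglinear(years_c: np.ndarray, deaths: np.ndarray,
                           population: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Newton/IRLS fit of log E[D] = log P + a + b*t for one age.

    Returns (coef, cov) where coef = (a, b) and cov is the inverse observed
    information.  Deterministic start at (log(sum D / sum P), 0).
    """
    X = np.column_stack([np.ones_like(years_c), years_c])
    offset = np.log(population)
    coef = np.array([np.log(deaths.sum() / population.sum()), 0.0])
    for _ in range(_MAX_ITER):
        mu = np.exp(offset + X @ coef)
        score = X.T @ (deaths - mu)
        info = X.T @ (mu[:, None] * X)
        step = np.linalg.solve(info, score)
        coef_new = coef + step
        if np.max(np.abs(step) / np.maximum(np.abs(coef_new), 1.0)) < _REL_TOL:
            coef = coef_new
            break
        coef = coef_new
    mu = np.exp(offset + X @ coef)
    info = X.T @ (mu[:, None] * X)
    cov = np.linalg.inv(info)
    return coef, cov


class PoissonTrendModel:
    """Scikit-learn-style estimator for the per-age Poisson mortality trend.

    Parameters
    ----------
    sex : label
        The sex stratum of the panel to fit.
    fit_window : (int, int)
        Inclusive year range of the pre-pandemic window (default 2010-2019).
    year_center : float, optional
        Centering constant for the year covariate.  Defaults to the window
        midpoint; predictions are invariant to this choice, it only
        conditions the solve.

    Attributes (after :meth:`fit`)
    ------------------------------
    ages_ : ndarray of fitted ages (or class lower bounds).
    coef_ : ndarray (n_ages, 2) of (intercept, slope) on the log-rate scale.
    cov_ : ndarray (n_ages, 2, 2) per-age coefficient covariances.
    deaths_ : ndarray of total deaths per age over the window.
    year_center_ : the centering constant actually used.
    """

    def __init__(self, sex=None, fit_window: tuple[int, int] = (2010, 2019),
                 year_center: float | None = None):
        self.sex = sex
        self.fit_window = fit_window
        self.year_center = year_center

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"sex": self.sex, "fit_window": self.fit_window,
                "year_center": self.year_center}

    def set_params(self, **params) -> "PoissonTrendModel":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        return (f"PoissonTrendModel(sex={self.sex!r}, fit_window={self.fit_window!r}, "
                f"year_center={self.year_center!r})")

    # -- estimation ---------------------------------------------------------
    def fit(self, panel: pd.DataFrame, y=None) -> "PoissonTrendModel":
        """Fit independent per-age Poisson trends on the window years."""
        lo, hi = self.fit_window
        sub = subset(panel, sex=self.sex)
        sub = sub[(sub["year"] >= lo) & (sub["year"] <= hi)]
        if sub.empty:
            raise KeyError(f"no records for sex={self.sex!r} in window {self.fit_window}")
        center = self.year_center if self.year_center is not None else (lo + hi) / 2.0
        ages, coefs, covs, totals = [], [], [], []
        for age, grp in sub.groupby("age"):
            d = grp["deaths"].to_numpy(dtype=float)
            if d.sum() == 0:
                raise SparseDataError(
                    f"age {age} has zero deaths over {lo}-{hi}; aggregate ages first")
            t = grp["year"].to_numpy(dtype=float) - center
            p = grp["population"].to_numpy(dtype=float)
            coef, cov = _fit_poisson_loglinear(t, d, p)
            ages.append(age)
            coefs.append(coef)
            covs.append(cov)
            totals.append(d.sum())
        order = np.argsort(ages)
        self.ages_ = np.asarray(ages)[order]
        self.coef_ = np.asarray(coefs)[order]
        self.cov_ = np.asarray(covs)[order]
        self.deaths_ = np.asarray(totals)[order]
        self.year_center_ = center
        return self

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted; call fit() first")

    # -- prediction ---------------------------------------------------------
    def predict_age_rates(self, year: int) -> pd.DataFrame:
        """Predicted age-specific rates and their log-scale variances.

        Extrapolation beyond the fit window is the intended use (predicting
        the no-pandemic counterfactual); the variance grows quadratically in
        the distance from the window centre.
        """
        self._check_fitted()
        t = float(year) - self.year_center_
        log_rate = self.coef_[:, 0] + self.coef_[:, 1] * t
        var_log = (self.cov_[:, 0, 0] + t ** 2 * self.cov_[:, 1, 1]
                   + 2.0 * t * self.cov_[:, 0, 1])
        return pd.DataFrame({"age": self.ages_, "rate": np.exp(log_rate),
                             "var_log": var_log})

    def predict_standardized_rate(self, year: int, ref_panel: pd.DataFrame,
                                  ref_year: int,
                                  age_range: tuple[float, float] | None = None
                                  ) -> StandardizedRate:
        """Predicted SMR over the reference population, with delta-method
        variance (per-age predictions are independent across ages)."""
        self._check_fitted()
        ref = subset(ref_panel, sex=self.sex, year=ref_year, age_range=age_range)
        if ref.empty:
            raise KeyError(f"no reference populations for sex={self.sex!r}, "
                           f"year {ref_year}")
        ref = ref.set_index("age").sort_index()
        pred = self.predict_age_rates(year).set_index("age")
        in_range = pred
        if age_range is not None:
            lo, hi = age_range
            in_range = pred[(pred.index >= lo) & (pred.index < hi)]
        if not ref.index.equals(in_range.index):
            raise PanelSchemaError("age supports of trend fit and reference panel differ")
        p_ref = float(ref["population"].sum())
        weights = ref["population"].to_numpy(dtype=float) / p_ref
        contrib = in_range["rate"].to_numpy() * weights
        value = float(contrib.sum())
        var_log = float((contrib ** 2 * in_range["var_log"].to_numpy()).sum()) / value ** 2
        return StandardizedRate(value=value, var_log=var_log, sex=self.sex,
                                year=year, ref_year=ref_year, age_range=age_range,
                                source="predicted")

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-age coefficient table (round-trips via :meth:`from_frame`)."""
        self._check_fitted()
        return pd.DataFrame({
            "sex": self.sex, "age": self.ages_,
            "intercept": self.coef_[:, 0], "slope": self.coef_[:, 1],
            "var_intercept": self.cov_[:, 0, 0], "var_slope": self.cov_[:, 1, 1],
            "cov_intercept_slope": self.cov_[:, 0, 1],
            "deaths": self.deaths_,
            "year_center": self.year_center_,
            "window_start": self.fit_window[0], "window_end": self.fit_window[1],
        })

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "PoissonTrendModel":
        sex = table["sex"].iloc[0]
        window = (int(table["window_start"].iloc[0]), int(table["window_end"].iloc[0]))
        model = cls(sex=sex, fit_window=window,
                    year_center=float(table["year_center"].iloc[0]))
        table = table.sort_values("age")
        model.ages_ = table["age"].to_numpy()
        model.coef_ = table[["intercept", "slope"]].to_numpy(dtype=float)
        n = len(table)
        cov = np.zeros((n, 2, 2))
        cov[:, 0, 0] = table["var_intercept"].to_numpy(dtype=float)
        cov[:, 1, 1] = table["var_slope"].to_numpy(dtype=float)
        cov[:, 0, 1] = cov[:, 1, 0] = table["cov_intercept_slope"].to_numpy(dtype=float)
        model.cov_ = cov
        model.deaths_ = table["deaths"].to_numpy(dtype=float)
        model.year_center_ = float(table["year_center"].iloc[0])
        return model


def fit_trend(panel: pd.DataFrame, sex, fit_window: tuple[int, int] = (2010, 2019),
              year_center: float | None = None) -> PoissonTrendModel:
    """Convenience wrapper: fit a :class:`PoissonTrendModel` on a panel."""
    return PoissonTrendModel(sex=sex, fit_window=fit_window,
                             year_center=year_center).fit(panel)
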