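# Methods

## Model and procedure

The package estimates how far mortality in a given year departs from the
past, using two comparators on the same standardized scale.

**Standardization.** All rates are directly age-standardized to the January-1
population of a fixed reference year *s* (default 2022): the reference
population supplies both the weights of the age-specific rates and the scale
on which excess deaths are expressed. The standardized rate is computed as
Σ *D<sub>i</sub>w<sub>i</sub>* / *P<sup>s</sup>* with
*w<sub>i</sub>* = *P<sub>i</sub><sup>s</sup>*/*P<sub>i</sub><sup>y</sup>*,
which makes the reference-year SMR equal the crude rate *exactly* in
floating point (each *w<sub>i</sub>* is 1.0), an identity asserted in the
tests. Death counts are treated as independent Poisson variables per age
stratum, giving the delta-method variance of the log rate
Σ *D<sub>i</sub>w<sub>i</sub>*²/(Σ *D<sub>i</sub>w<sub>i</sub>*)², and 1/ΣD
for the crude rate. Zero-death strata contribute zero to both sums (no
pseudo-counts); a rate with zero total deaths is flagged degenerate and
refuses to enter any interval computation.

**Calendar corrections.** Leap-year deaths are multiplied by 365/366
(default leap set 2012/2016/2020 within the default study window). A year
reported only as statistical weeks is aligned to the calendar year by
adding `lead_fraction` (default 2/7) of the first week's deaths and removing
`tail_fraction` (default 1/7) of the last week's — the alignment for a
52-week year starting January 3 and ending January 1. When both corrections
apply, the weekly alignment runs first.

**Trend.** Per sex, a Poisson log-linear GLM with age as factor, a linear
year term, full age × year interaction and log-population offset. Since
every age carries its own intercept and slope, the joint fit decomposes
exactly into independent two-parameter fits per age; the package solves each
by Newton's method on the log-likelihood (relative coefficient tolerance
1e-10, at most 100 iterations, deterministic start at (log(ΣD/ΣP), 0)) with
covariance from the observed information. The test suite verifies the
decomposition against a joint interaction-design GLM fitted by statsmodels
(agreement to 1e-6) and against a generic quasi-Newton optimizer. The year
covariate is centered at the fit-window midpoint for conditioning;
predictions are invariant to the centering (tested to 1e-8). Plain Poisson
likelihood, no overdispersion correction: the intervals inherit the Poisson
assumption. Cross-age covariances of the predictions are zero by
construction (independent per-age fits), so the predicted-SMR variance is
the weighted sum of per-age variances. Annual granularity only: in a Poisson
regression a seasonal term uncorrelated with the year trend would leave
expected annual totals unchanged, so weekly/monthly granularity buys nothing
for annual excess.

**Excess.** EM = 100(m_y/m_comp − 1)%, CI =
100·exp{log(m_y/m_comp) ± z·√(V_y + V_comp)} − 100 with z = 1.96 held as the
conventional constant (configurable multiplier), and ED =
(m_y − m_comp)·P^s. Variances add because the comparator uses distinct
death counts (level comparator) or an independently fitted model (trend
comparator). Age-class stratification restricts the sums to half-open
classes [a, b) with weights renormalized within the class, which makes
class excess deaths sum exactly to the all-ages figure for any partition. A
class with a degenerate comparator is reported with NaN interval bounds
without aborting the remaining classes. "Significant" means the 95% CI
excludes zero.

**Life table.** Hazards pooled into 19 five-year classes (0–4 … 85–89,
90+), constant within class; ages 91–110 inherit the 90+ rate. Life
expectancy is the closed-form sum e = ½ + Σ_{l=start}^{110}
exp(−Σ_{i=start}^{l} ṁ_i); the ½ is the half year lived in the year of
death (no separate infant-mortality a₀ refinement). Residual life
expectancy at 50 uses the same formula started at 50, including the ½ —
the direct analogue of the formula at birth. Predicted life expectancy
replaces observed class rates with trend-predicted single-age rates
averaged within classes using the *current year's* population weights (the
exposures actually at risk). Losses are 12·(e_y − e_comp) months, negative
for losses.

## Synthetic data: what it emulates and what it does not

`SimulationConfig`/`generate_panel` emulate statistical-office extracts:
per-sex deaths by single age 0–100+ (Poisson around a deterministic rate
surface, clipped at the population), January-1 populations growing
deterministically at 0.75%/yr, Gompertz baseline log-rates at the window
midpoint — (−10.576, 0.095) for men and (−11.328, 0.10) for women,
calibrated so the implied life expectancy at birth is ≈81/≈85 years — and
constant per-age log-rate slopes of −0.02/yr (men) and −0.01/yr (women).
Shocks multiply rates in chosen years. `generate_weekly` splits a year's
deaths multinomially over 52/53 weeks (cosine seasonality peaking in early
January plus optional Gaussian pulses) in the coarse reporting classes
0–19, 20–39, 40–64, 65–79, 80+, conserving annual class totals exactly;
5-year classes with an open 90+ can be requested for the final-year layout.
The default pyramid pop0(i) = 60000·exp(−(i/70)⁴) gives ≈3.9 M per sex.

Not emulated: migration and cohort bookkeeping (populations evolve
deterministically), cause-of-death structure, true age-varying trend
slopes, reporting delays, or correlation between weekly seasonality and
age. Passing tests therefore demonstrate the *estimators'* correctness and
calibration under the model's own assumptions (Poisson counts, log-linear
trends), not robustness to overdispersion or trend misspecification in real
registry data.

## Numerical and design choices

- Ages are completed years, classes half-open [a, b) with the last class
  open; panels are truncated/collapsed to a common top class (default 100+)
  before rate computation, since deaths and population sources may top out
  at different open classes.
- Reporting precision: EM/CI one decimal in %, ED whole counts, losses one
  decimal in months; rounding half-away-from-zero.
- The standardized-weekly-deaths formula scales each class's deaths by
  P^s/P^y (reference over current population), the orientation that makes
  years comparable and matches the SMR weighting convention.
- Weekly-only final years are folded into the annual panel at the weekly
  table's class resolution, apportioning each class's deaths between sexes
  by that year's population shares (weekly sources carry no sex split).
- The pipeline is deterministic given its inputs; all randomness sits in
  the generator behind a single integer seed.

## Problem sizes used in the test and acceptance runs

Simulation-based checks run at sizes chosen to make their Monte-Carlo error
small relative to the tested tolerance: 2000 replicates for interval
coverage and variance calibration (two strata, ~1000 expected deaths/year),
50 seeds × 21 ages at 10⁶ population per age for slope recovery, 30–40
seeded end-to-end runs (≈20k–60k annual deaths) for the null and +8%-shock
power checks, and 300 reduced-age runs for prediction-interval coverage.

## Known limitations

- No overdispersion handling: real all-cause death counts are often
  slightly overdispersed, which would make the Poisson intervals
  anti-conservative.
- The trend comparator is counterfactual by construction; its validity
  rests on the log-linear extrapolation, and alternative windows or curved
  trends will move the estimates.
- The life table has no terminal-age refinement beyond extending the 90+
  hazard to age 110, and the ½-year convention is used at every start age.
- Weekly standardization assumes class populations are exact denominators;
  within-year population change is ignored.
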