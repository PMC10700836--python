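# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Exposure windows and reference temperatures

The exposure of a person-wave observation is the arithmetic mean
temperature over the 30 calendar days **ending on and including** the
interview date. Descriptions of such windows are sometimes ambiguous
(a "30-day span" quoted with endpoint dates can span 31–33 days); we fix
the convention as the closed window `[date − 29, date]` and expose
`window_days` everywhere, so any other convention is one parameter away.

Historical references transpose the window's *month–day boundaries* to
earlier years rather than day-of-year offsets, preserving the calendar
identity of the window; February 29 inside a transposed window simply does
not exist in non-leap years and the mean uses the days actually present.
The schemes:

| scheme | years averaged | notes |
|---|---|---|
| lifetime | birth year … interview year − 1 | the individualized reference |
| fixed_period(a, b) | a … min(b, interview − 1) | truncation at the interview year warns |
| preceding_years(n) | interview − n … interview − 1 | equals lifetime iff n = age |
| cumulative_age(m) | birth … min(birth + m − 1, interview − 1) | saturates to lifetime at m ≥ age |

Every scheme excludes the interview year itself: the reference is what the
respondent had experienced *before* the current window. The years-missed
rate `|age − n| / max(age, n)` covers both directions of mismatch
(under-coverage when n < age, over-inclusion when n > age) with a single
formula that reproduces both worked cases (50 vs 25 years → 50 %; 20 vs 25
→ 20 %).

Day-count anomalies compare each window day against that calendar day's
mean over a historical year range, counting strict exceedances.

## Station-to-county interpolation

Inverse-distance weighting with power 2 over **all** stations, weights
normalized to sum to one; a county within 1 m of a station snaps to the
station value exactly. No k-nearest cutoff and no elevation adjustment:
the interpolation is a convex combination, so county values always lie
inside the station range. County series refuse silent imputation — a
missing calendar day is a recorded gap, and any window or reference that
touches one raises a named error rather than filling it.

## The synthetic generator

The generator is the package's definition of the study conditions, not a
tuning knob.

- **Weather** (1951–2018 by default): regional base temperature (14–20 °C
  across four regions), a seasonal cosine with 11 °C amplitude peaking in
  mid-July, a secular warming trend of 0.02 °C/yr (the ~0.2 °C/decade rate
  of recent decades), a per-station microclimate offset (SD 0.5 °C), a
  station-by-year anomaly (SD 0.8 °C) carrying interannual variability —
  one August warmer than the next — and day-to-day noise (SD 2 °C).
  The station-year term is what gives anomalies their cross-sectional
  variance; without it, 30-day averaging washes daily noise out and the
  anomaly regressor degenerates.
- **Geography**: stations and counties uniform on a 1000 km × 1000 km
  plane divided into vertical region bands. Planar kilometres avoid
  geodesy; the IDW contract is unchanged. Default 10 stations / 30
  counties: a sparser station network than the real ~5:1 station:county
  ratio, chosen because all-station IDW over a dense network averages away
  exactly the local station-year shocks that identify the effect.
- **Panel**: 3000 respondents × waves 2010/2014/2018, birth years
  1955–1990, fixed county for life, interview dates uniform May 1 – Oct 31
  (the summer/autumn fieldwork season; the true survey's date distribution
  beyond season is not public, so the window is a modelling choice).
  Controls: log income (drifting), marital status, education, employment,
  two-week discomfort, lognormal survey weights.
- **Outcome**: `y = 3.0 − 0.023 · anomaly + controls·rho + gamma_i +
  theta_date + county×date shock (SD 0.1) + eps (SD 1.0)`. The
  county-by-date shock gives clustered inference something real to absorb.
  Discretization to the 1–5 scale is off by default so recovery tests are
  clean; switching it on censors the tails and attenuates recovered slopes,
  a property the suite tests qualitatively.
- **Scenarios**: per (scenario, model, region) annual series 1950–2100; a
  shared 0.02 °C/yr history to 2014, then "netzero" increments shrinking
  linearly to zero by 2045, "middle" at a steady 0.03 °C/yr, "high"
  accelerating 0.03 → 0.08 °C/yr. Inter-model spread enters through a
  per-model level offset (SD 0.3 °C) and increment multiplier (SD 0.10);
  paths are smooth, so catch-up detection is not confounded by year noise.
- **Average age**: linear, 38 years in 2020 drifting +0.15/yr (an ageing
  population reaching 50 by 2100); a constant-age option feeds the
  closed-form checks.

All generators route randomness through one seeded `numpy` generator per
call and are byte-reproducible.

## Estimation

Fixed effects are absorbed by alternating weighted group demeaning over the
individual and exact-interview-date dimensions, iterated to a 1e-10 sweep
tolerance (cap 1000). Exact-date dummies nest year, month, day-of-week and
holiday effects on synthetic data. Rows that are singletons in either
dimension are dropped (iteratively) and counted: they are demeaned to zero
and only distort finite-sample corrections. Columns whose demeaned weighted
SD falls below 1e-8 — age and schooling, which are exact functions of
person + date — are reported as absorbed and removed rather than tripping
the rank check; genuine rank deficiency raises an error naming the
collinear columns found by pivoted QR.

WLS is solved by QR on the sqrt-weight-scaled design. The covariance is
Cameron–Gelbach–Miller: `V = V_county + V_date − V_county×date`, each term
a sandwich with finite-cluster correction `G/(G−1) · (N−1)/(N−K)` (the
reference implementation's convention; the exact correction used by the
original analysis is unstated, so we adopt the standard one and flag it).
K counts the slim post-absorption design columns — the convention for
fixed effects nested within cluster dimensions, as persons nest in
counties and dates in date clusters here. If the combined matrix is not
positive semi-definite, negative eigenvalues are floored at zero and the
repair is flagged in the fit metadata. Inference uses a t distribution
with `min(G) − 1` degrees of freedom. No multiple-testing adjustment is
applied; tables print per-coefficient stars at 0.01/0.05/0.1.

The alternating-projection route is the scalable estimator; the
dummy-variable regression is retained in the test suite as the
small-instance oracle (equality to 1e-8 on instances ≤ 200 rows), with
statsmodels' cluster sandwiches as the independent covariance reference.

## Anomaly model vs location-fixed-effects model

A location-FE temperature-level model identifies the slope from the gap
between current temperature and the location's average over the data
coverage period. We operationalize that comparison with the coverage
period set to the residents' common lifetime span. When, within every
city, (1) all interviews share one date, (2) all respondents share one
age, and (3) the interview falls after everyone's birth month, the
individualized-anomaly regressor is *row-identical* to the
coverage-demeaned temperature regressor, so the two estimates agree to
machine precision; violating any condition breaks the identity and the
estimates separate. The simulation uses a deliberately large stylized
effect (−0.5) because the check is algebraic — what matters is exact
agreement versus separation, not the effect's size. Note the equality is
a statement about the written demeaning algebra, not about the sample
demeaning an OLS city-dummy fit would perform across waves (under which
the lifetime reference moves between waves and exact equality cannot
hold); this is the package's resolution of a genuinely loose step in the
source derivation.

## Projection

The representative agent's reference uses *annual mean* temperatures, not
30-day windows — scenario trajectories are annual and the agent has no
interview date; this divergence from the estimation-side window is
deliberate and documented. Average age is rounded to the nearest integer
year for birth-year arithmetic (fractional-age interpolation is available).
Scenario paths start in 2015, so each trajectory carries a 1950–2014
historical backcast consistent with its region baseline; projections
without sufficient history raise an error telling the caller to supply
one. The catch-up year is the first year after which the ensemble
updating-reference anomaly stays below 0.05 °C in absolute value — no
numeric criterion for "fully adapted" exists in the source, so 0.05 °C is
the package default and a parameter. Impacts are exactly
`beta_hat × anomaly`, ensemble means are arithmetic over models.

## Problem sizes

The Monte-Carlo recovery experiments run 100 replicates of 3000 × 3
observations on the 10-station/30-county geography (about half a minute);
the qualitative sweep comparisons use 12 paired replicates; oracle checks
use ≤ 200-row instances. These sizes make the suite's Monte-Carlo bands
(2 standard errors) tight enough to be meaningful while keeping a full
run fast.

## What passing tests do and do not show

The generator emulates the *structure* of the real setting — station
records with seasonality, warming and interannual variability; a
non-migrating three-wave panel; a linear-in-anomaly outcome with
individual and date heterogeneity — but not real geography, demography,
spatially correlated weather systems, migration, attrition, or the ordinal
measurement of well-being (treated linearly, as in the source analysis).
Recovery of the generating coefficient therefore validates the pipeline's
internal consistency (exposure construction, demeaning, weighting,
clustering), not the empirical magnitude of any real-world effect; the
published point estimates come from restricted microdata and are not
reproducible here. Directional reproductions (fixed-period references
inflating anomalies, attenuation under short reference windows, net-zero
catch-up) are mechanical consequences of warming plus the reference
definitions and should be read as consistency checks of the same
mechanisms the source describes.

## Known limitations

- Wet-bulb or maximum-temperature exposures are accepted only as
  pre-computed alternative columns; no humidity physics.
- No spatial-HAC (Conley) errors, instrumental variables, or ordered
  response models.
- Reference windows for respondents born before the weather record begin
  raise coverage errors rather than extrapolating (truncate-and-flag).
- The IDW has no k-nearest cutoff, so very dense station networks smooth
  local variability.
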