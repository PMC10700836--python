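# acclimate

Individualized temperature-anomaly exposure modelling for subjective
well-being (SWB), with two-way fixed-effects estimation, adaptation-aware
climate projection, and a synthetic-data generator that supplies every
input with known ground truth.

## The problem

How much does unusually hot weather hurt self-reported well-being — and how
much of that hurt fades as people acclimatize? Fixed-effects panel studies
of weather and well-being usually identify the temperature effect from
deviations of a location's temperature around its long-run mean, which
imposes one shared "normal" on everyone who lives there. People differ:
someone who has lived through fifty summers in a county has a different
internal reference than a twenty-year-old in the same county. This package
implements the *individualized anomaly* design: each respondent's exposure
is measured against their own lifetime temperature history, built from
their birth year, their (fixed) location, and the calendar window of their
interview.

The estimating equation is a weighted fixed-effects panel regression

    y_ijt = alpha + beta1 * f(temp_ijt) + X_ijt rho + W_ijt sigma
            + gamma_i + theta_(j)(t) + eps_ijt

where `y_ijt` is a 1–5 well-being score of person `i` in county `j` at
interview date `t`, `gamma_i` and `theta_(j)(t)` are individual and
interview-date fixed effects, `X` are individual controls, `W` weather
controls (second-order polynomials), and standard errors are two-way
clustered by county and date. The temperature term `f(temp)` can be:

- **anomaly** — the 30-day pre-interview mean minus the *lifetime
  reference*: the same calendar window averaged over every year from the
  respondent's birth year to the year before the interview
  (`Anomalies_jt(i) = temp_ijt − hist_temp_ijt`). A 25-year-old interviewed
  in late August 2014 is referenced against the Augusts of 1989–2013.
- **split** — the anomaly's positive ("hotter-than-expected") and negative
  ("colder-than-expected") parts entered jointly;
- **day_count** — days in the window above their calendar-day historical
  mean;
- **bins** — day counts in 3 °C temperature bins relative to the omitted
  comfortable 18–21 °C bin.

Alternative reference schemes (a fixed 1980–2000 period, the *n* preceding
years, cumulative years of life up to a maximum age) quantify what is lost
when individualized histories are unavailable, summarized by the
years-missed rate `|age − n| / max(age, n)`.

On the projection side, a representative citizen of (rising) average age is
walked through ensemble scenario trajectories to 2100. Her anomaly each
year is the annual temperature minus either a *continuously updating*
lifetime reference (acclimatization) or a reference frozen at the 1980–2000
mean; multiplying by the estimated marginal effect turns anomalies into
well-being impacts, and the *catch-up year* marks when adaptation has fully
absorbed the warming under a given emissions path.

All estimation is implemented from first principles: alternating-projection
within transformation, weighted least squares, and Cameron–Gelbach–Miller
two-way cluster-robust covariance, each cross-checked in the test suite
against independent routes (dummy-variable OLS, statsmodels sandwiches).

## Worked example

```python
import numpy as np
import acclimate as ac

stations, counties = ac.generate_geography(n_stations=10, n_counties=30, n_regions=4, seed=11)
weather = ac.simulate_station_weather(stations, ac.ClimateParams(), seed=12)
series = ac.interpolate_county_daily(weather, stations, counties)

panel = ac.simulate_panel(counties, n_individuals=3000, seed=1)
anomalies = ac.build_anomaly_set(panel, series, ac.ReferenceSpec("lifetime"))
panel = ac.simulate_swb(panel, anomalies["anomaly"], ac.DGPParams(), seed=2)

exposures = ac.build_exposures(panel, series)
fit = ac.fit_model(panel, exposures, anomalies, ac.ModelSpec())

traj = ac.generate_projection_scenarios(range(4), n_models=20, seed=3)
ages = ac.generate_age_trajectory()
proj = ac.project_impacts(traj, ages, -0.0227)
```

prints, with the surrounding `print` calls:

```
mean [SD] anomaly: 0.23 [0.76] degC
one draw: beta = 0.0067 (clustered SE 0.0182), N = 9000, clusters = {'county_id': 30, 'interview_date': 552}
20-replicate mean beta: -0.0200 (true -0.0230)
catch-up year by scenario: {'high': None, 'middle': None, 'netzero': 2065}
```

Reading this: anomalies average +0.23 °C because the record warms, so the
recent window tends to sit above each person's lifetime mean. A single
draw of the outcome is noisy relative to an effect of −0.023 (its clustered
confidence interval easily covers the truth); averaging the estimator over
20 regenerated outcomes lands near the generating value, which is the
package's central recovery property (the test suite runs 100 replicates).
Under the plateauing net-zero scenario the updating-reference anomaly falls
below 0.05 °C for good in 2065 — adaptation catches up — while under
sustained warming it never does.

The same pipeline is scriptable end to end:

```bash
acclimate all --config config.yaml --out runs/demo
```

which writes `stations.csv`, `weather_daily.csv`, `county_daily.csv`,
`panel.csv`, `exposures.csv`, `anomalies.csv`, `fit.json`, `sweep.csv`,
`projection.csv`, `projection_summary.csv`, a rendered coefficient table,
and a checksummed run manifest (schemas in `docs/formats.md`).

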