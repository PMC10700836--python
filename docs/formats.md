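# Artifact schemas

All intermediate artifacts are plain CSV (ISO-8601 dates, temperatures in
°C) or JSON, written to the run's output directory and recorded with
SHA-256 checksums in `manifest.json`.

## stations.csv / counties.csv
`station_id|county_id, x, y, region_id` — planar coordinates in km.

## weather_daily.csv
`station_id, date, temp, wind, humidity, precip, sun_hours` — one row per
station-day.

## county_daily.csv
`county_id, date, temp, wind, humidity, precip, sun_hours` — IDW-interpolated
daily county series.

## panel.csv
`person_id, county_id, birth_year, wave, interview_date, age, log_income,
married, education, employed, discomfort, weight` plus, after the build
stage, `swb_latent` and `swb`. One row per person-wave.

## exposures.csv
`wind_mean, humidity_mean, precip_mean, sun_hours_mean` — 30-day window
means aligned row-for-row with `panel.csv`; with a bins specification also
`bin_lt_0, bin_0_3, …, bin_ge_30` day counts.

## anomalies.csv
`person_id, wave, scheme, current_mean, reference_mean, anomaly,
positive_part, negative_part, reference_years_used` (optionally
`day_count_above`), aligned row-for-row with `panel.csv`.

## fit.json
Per fitted term (`anomaly`, `split`, …): coefficients, clustered SEs,
p-values, covariance, observation and cluster counts, demeaning iterations
and tolerance, absorbed columns, PSD-repair flag; top-level `beta_hat`
carries the anomaly coefficient used by the projection stage.

## sweep.csv
`scheme, param, beta, se, pvalue, ci_lower, ci_upper, mean_years_missed,
n_obs` — one row per reference-construction grid point.

## scenarios.csv
`scenario, model, region, year, temp` — annual series 1950–2100 per
scenario/model/region (history included).

## ages.csv
`year, avg_age`.

## projection.csv
`scenario, model, region, year, temp, anomaly_updating, anomaly_fixed,
impact_updating, impact_fixed` — per-path detail.

## projection_summary.csv
Per scenario-year national ensemble means of the four quantities plus
`anomaly_difference` (fixed − updating) and the scenario's `catch_up_year`
(empty when adaptation never catches up).

## manifest.json
Seed, per-stage seed chain, stages run, and per-artifact SHA-256, byte and
row counts.
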