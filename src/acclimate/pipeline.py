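"""End-to-end pipeline: simulate -> build -> estimate -> sweep -> project.

A single ``RunConfig`` drives every stage; all intermediate artifacts are
plain CSV/JSON in the output directory (schemas in ``docs/formats.md``), so
any stage can be re-run from the files of the previous ones. The run
manifest records every artifact with a SHA-256 checksum, row counts and the
per-stage seed chain, making a rerun under the same config byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as sd
from .anomalies import ReferenceSpec, build_anomaly_set
from .estimation import ModelSpec, fit_model, reference_sweep
from .projection import plot_projection, project_impacts
from .weather import BinSpec, CountyDailySeries, build_exposures, interpolate_county_daily

log = logging.getLogger("acclimate")

STAGES = ("simulate", "build", "estimate", "sweep", "project")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults give the standard study setup."""

    seed: int = 0
    n_stations: int = 10
    n_counties: int = 30
    n_regions: int = 4
    climate: sd.ClimateParams = field(default_factory=sd.ClimateParams)
    waves: tuple[int, ...] = (2010, 2014, 2018)
    n_individuals: int = 3000
    birth_year_range: tuple[int, int] = (1955, 1990)
    interview_window: tuple[tuple[int, int], tuple[int, int]] = ((5, 1), (10, 31))
    dgp: sd.DGPParams = field(default_factory=sd.DGPParams)
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    model_terms: tuple[str, ...] = ("anomaly", "split")
    sweep_grid: tuple[int, ...] = (2, 5, 10, 15, 20, 25, 30, 40)
    n_climate_models: int = 20
    scenarios: tuple[str, ...] = sd.SCENARIOS
    fixed_window: tuple[int, int] = (1980, 2000)
    catch_up_threshold: float = 0.05
    run_sweep: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "climate" in d and isinstance(d["climate"], dict):
            c = dict(d["climate"])
            if "regional_base_temp" in c:
                c["regional_base_temp"] = tuple(c["regional_base_temp"])
            d["climate"] = sd.ClimateParams(**c)
        if "dgp" in d and isinstance(d["dgp"], dict):
            d["dgp"] = sd.DGPParams(**d["dgp"])
        if "reference" in d and isinstance(d["reference"], dict):
            r = dict(d["reference"])
            if "fixed_period" in r:
                r["fixed_period"] = tuple(r["fixed_period"])
            d["reference"] = ReferenceSpec(**r)
        for key in ("waves", "model_terms", "sweep_grid", "scenarios",
                    "birth_year_range", "fixed_window"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "interview_window" in d and isinstance(d["interview_window"], list):
            d["interview_window"] = tuple(tuple(p) for p in d["interview_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES) + 2)
    names = [*STAGES, "swb", "scenarios"]
    return {name: int(s % (2 ** 31)) for name, s in zip(names, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)
    log.info("wrote %s (%d rows)", path.name, len(df))


def _require(outdir: Path, name: str, stage: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {name}, which is missing from {outdir}; "
            f"run the earlier stages first")
    return p


def _load_series_map(outdir: Path, stage: str) -> dict:
    df = pd.read_csv(_require(outdir, "county_daily.csv", stage), parse_dates=["date"])
    variables = [c for c in df.columns if c not in ("county_id", "date")]
    return {
        cid: CountyDailySeries.from_frame(grp, cid, variables=variables)
        for cid, grp in df.groupby("county_id")
    }


def _load_panel(outdir: Path, stage: str) -> pd.DataFrame:
    return pd.read_csv(_require(outdir, "panel.csv", stage), parse_dates=["interview_date"])


def stage_simulate(config: RunConfig, outdir: Path, seeds) -> None:
    stations, counties = sd.generate_geography(
        config.n_stations, config.n_counties, config.n_regions, seeds["simulate"])
    weather = sd.simulate_station_weather(stations, config.climate, seeds["simulate"] + 1)
    panel = sd.simulate_panel(
        counties, config.waves, config.n_individuals, config.birth_year_range,
        interview_window=config.interview_window, seed=seeds["simulate"] + 2)
    scen = sd.generate_projection_scenarios(
        sorted(counties["region_id"].unique()), config.scenarios,
        config.n_climate_models, seed=seeds["scenarios"],
        base_temps=config.climate.regional_base_temp,
        history_trend=config.climate.warming_trend)
    ages = sd.generate_age_trajectory()
    _write_csv(stations, outdir / "stations.csv")
    _write_csv(counties, outdir / "counties.csv")
    _write_csv(weather, outdir / "weather_daily.csv")
    _write_csv(panel, outdir / "panel.csv")
    _write_csv(scen, outdir / "scenarios.csv")
    _write_csv(ages, outdir / "ages.csv")


def stage_build(config: RunConfig, outdir: Path, seeds) -> None:
    stations = pd.read_csv(_require(outdir, "stations.csv", "build"))
    counties = pd.read_csv(_require(outdir, "counties.csv", "build"))
    weather = pd.read_csv(_require(outdir, "weather_daily.csv", "build"), parse_dates=["date"])
    panel = _load_panel(outdir, "build")

    series_map = interpolate_county_daily(weather, stations, counties)
    county_daily = pd.concat(
        [
            pd.DataFrame({"county_id": cid,
                          "date": pd.date_range(s.start, s.end, freq="D"),
                          **{v: s._values[v] for v in s.variables}})
            for cid, s in series_map.items()
        ],
        ignore_index=True,
    )
    _write_csv(county_daily, outdir / "county_daily.csv")

    exposures = build_exposures(panel, series_map, config.reference.window_days,
                                bin_spec=BinSpec() if "bins" in config.model_terms else None)
    anoms = build_anomaly_set(panel, series_map, config.reference)
    panel = sd.simulate_swb(panel, anoms["anomaly"].to_numpy(), config.dgp, seeds["swb"])
    _write_csv(panel, outdir / "panel.csv")
    _write_csv(pd.concat([exposures], axis=1), outdir / "exposures.csv")
    _write_csv(anoms, outdir / "anomalies.csv")


def stage_estimate(config: RunConfig, outdir: Path, seeds) -> None:
    panel = _load_panel(outdir, "estimate")
    if "swb" not in panel.columns:
        raise FileNotFoundError("panel.csv has no outcome column; run the build stage first")
    exposures = pd.read_csv(_require(outdir, "exposures.csv", "estimate"))
    anoms = pd.read_csv(_require(outdir, "anomalies.csv", "estimate"))
    fits = {}
    for term in config.model_terms:
        spec = ModelSpec(term=term, reference=config.reference)
        fits[term] = fit_model(panel, exposures, anoms, spec)
        log.info("fit '%s': %s", term,
                 {c: round(float(fits[term].params[c]), 5) for c in fits[term].term_columns})
    payload = {name: fit.to_dict() for name, fit in fits.items()}
    if "anomaly" in fits:
        payload["beta_hat"] = float(fits["anomaly"].params["anomaly"])
    with open(outdir / "fit.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    from .report import render_tables
    (outdir / "tables.txt").write_text(render_tables(fits))


def stage_sweep(config: RunConfig, outdir: Path, seeds) -> None:
    if not config.run_sweep:
        log.info("sweep disabled in config")
        return
    panel = _load_panel(outdir, "sweep")
    exposures = pd.read_csv(_require(outdir, "exposures.csv", "sweep"))
    series_map = _load_series_map(outdir, "sweep")
    spec = ModelSpec(term="anomaly", reference=config.reference)
    table = reference_sweep(panel, series_map, spec, config.sweep_grid, exposures)
    _write_csv(table, outdir / "sweep.csv")


def stage_project(config: RunConfig, outdir: Path, seeds) -> None:
    fit_path = _require(outdir, "fit.json", "project")
    with open(fit_path) as fh:
        payload = json.load(fh)
    if "beta_hat" not in payload:
        raise FileNotFoundError(
            "fit.json carries no anomaly coefficient; run the estimate stage "
            "with the 'anomaly' term first")
    beta = payload["beta_hat"]
    scen = pd.read_csv(_require(outdir, "scenarios.csv", "project"))
    ages = pd.read_csv(_require(outdir, "ages.csv", "project"))
    result = project_impacts(scen, ages, beta, config.fixed_window, config.catch_up_threshold)
    _write_csv(result.detail, outdir / "projection.csv")
    summary = result.national.copy()
    summary["catch_up_year"] = summary["scenario"].map(
        {k: (v if v is not None else "") for k, v in result.catch_up.items()})
    _write_csv(summary, outdir / "projection_summary.csv")
    plot_projection(result, outdir / "projection.png")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build": stage_build,
    "estimate": stage_estimate,
    "sweep": stage_sweep,
    "project": stage_project,
}


def run_pipeline(config: RunConfig, outdir, stages=STAGES) -> dict:
    """Run the requested stages and return the manifest.

    Any stage failure aborts with the stage name prefixed to the error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed)
    config.to_yaml(outdir / "config.yaml")
    try:
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
            log.info("stage %s starting", stage)
            try:
                _STAGE_FUNCS[stage](config, outdir, seeds)
            except FileNotFoundError as exc:
                raise FileNotFoundError(f"[stage {stage}] {exc}") from exc
            except Exception as exc:
                raise RuntimeError(f"[stage {stage}] {exc}") from exc
            log.info("stage %s done", stage)
        manifest = {
            "seed": config.seed,
            "stage_seeds": seeds,
            "stages_run": list(stages),
            "artifacts": {},
        }
        for p in sorted(outdir.iterdir()):
            if p.suffix in {".csv", ".json", ".yaml", ".txt", ".png"} and p.name != "manifest.json":
                entry = {"sha256": _sha256(p), "bytes": p.stat().st_size}
                if p.suffix == ".csv":
                    with open(p) as fh:
                        entry["rows"] = sum(1 for _ in fh) - 1
                manifest["artifacts"][p.name] = entry
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
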