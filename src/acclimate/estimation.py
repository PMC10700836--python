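"""Two-way fixed-effects weighted least squares with two-way clustered errors.

The estimator behind every specification is the same: absorb individual and
interview-date fixed effects by alternating weighted demeaning (the within
transformation), solve weighted least squares on the demeaned design, and
form a Cameron-Gelbach-Miller two-way cluster-robust covariance
V = V_county + V_date - V_(county x date), each term a sandwich with its own
finite-cluster correction G/(G-1) * (N-1)/(N-K). Everything is implemented
directly on numpy; an independent dummy-variable / reference-library route
exists only in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .anomalies import ReferenceSpec, build_anomaly_set, years_missed_rate
from .errors import CollinearityError, ConvergenceError
from .weather import BinSpec

__all__ = [
    "ModelSpec",
    "ModelFit",
    "within_transform",
    "fit_wls",
    "twoway_cluster_cov",
    "fe_wls",
    "fit_model",
    "stratified_fit",
    "reference_sweep",
]

INDIVIDUAL_CONTROLS = ("log_income", "age", "married", "education", "employed", "discomfort")
WEATHER_CONTROLS = ("wind_mean", "humidity_mean", "precip_mean", "sun_hours_mean")
ABSORBED_TOL = 1e-8  # weighted SD below which a demeaned column counts as absorbed


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and how to cluster."""

    outcome: str = "swb"
    term: str = "anomaly"  # anomaly | split | day_count | bins
    reference: ReferenceSpec = ReferenceSpec()
    bin_spec: BinSpec = BinSpec()
    fixed_effects: tuple[str, ...] = ("person_id", "interview_date")
    individual_controls: tuple[str, ...] = INDIVIDUAL_CONTROLS
    weather_controls: tuple[str, ...] = WEATHER_CONTROLS
    weather_poly_order: int = 2
    weights: str = "weight"
    clusters: tuple[str, ...] = ("county_id", "interview_date")

    def __post_init__(self):
        if self.term not in {"anomaly", "split", "day_count", "bins"}:
            raise ValueError(f"unknown temperature term {self.term!r}")
        if len(self.clusters) < 1:
            raise ValueError("at least one cluster dimension required")

    def term_columns(self) -> list[str]:
        if self.term == "anomaly":
            return ["anomaly"]
        if self.term == "split":
            return ["positive_part", "negative_part"]
        if self.term == "day_count":
            return ["day_count_above"]
        omitted = f"bin_{self.bin_spec.omitted_label()}"
        return [f"bin_{lab}" for lab in self.bin_spec.labels() if f"bin_{lab}" != omitted]


@dataclass
class ModelFit:
    """Coefficients, clustered covariance and fit metadata."""

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_clusters: dict[str, int]
    residuals: np.ndarray
    term_columns: list[str]
    fe_iterations: int = 0
    fe_delta: float = 0.0
    singletons_dropped: int = 0
    absorbed_columns: list[str] = field(default_factory=list)
    psd_repaired: bool = False
    df_inference: int = 1

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues.to_numpy()
        return pd.Series(2 * stats.t.sf(np.abs(t), self.df_inference), index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        q = stats.t.ppf(0.5 + level / 2, self.df_inference)
        return pd.DataFrame(
            {"lower": self.params - q * self.se, "upper": self.params + q * self.se}
        )

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se": self.se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "cov": {c: self.cov[c].to_dict() for c in self.cov.columns},
            "n_obs": int(self.n_obs),
            "n_clusters": {k: int(v) for k, v in self.n_clusters.items()},
            "term_columns": self.term_columns,
            "fe_iterations": int(self.fe_iterations),
            "fe_delta": float(self.fe_delta),
            "singletons_dropped": int(self.singletons_dropped),
            "absorbed_columns": self.absorbed_columns,
            "psd_repaired": bool(self.psd_repaired),
            "df_inference": int(self.df_inference),
        }


def _codes(values) -> np.ndarray:
    return pd.factorize(np.asarray(values))[0]


def drop_singletons(df: pd.DataFrame, fe_dims) -> tuple[pd.DataFrame, int]:
    """Iteratively drop rows that are alone in any fixed-effect group.

    Such rows are demeaned to exactly zero and carry no information; keeping
    them only distorts the N entering the finite-sample corrections.
    """
    dropped = 0
    while True:
        mask = np.ones(len(df), dtype=bool)
        for dim in fe_dims:
            counts = df[dim].map(df[dim].value_counts())
            mask &= counts.to_numpy() > 1
        if mask.all():
            return df, dropped
        dropped += int((~mask).sum())
        df = df.loc[mask]
        if len(df) == 0:
            raise ValueError("all rows dropped as fixed-effect singletons")


def within_transform(
    df: pd.DataFrame,
    columns,
    fe_dims=("person_id", "interview_date"),
    weights: str | None = "weight",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Absorb fixed effects by alternating weighted group demeaning.

    Repeatedly subtracts weighted group means along each dimension until the
    largest adjustment in a full sweep falls below ``tol``. Returns the
    demeaned copy (only ``columns`` change) and an info dict with the sweep
    count, final delta and singleton-drop count. One FE dimension converges
    in a single sweep by construction.
    """
    df, n_dropped = drop_singletons(df, fe_dims)
    w = df[weights].to_numpy(dtype=float) if weights else np.ones(len(df))
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    codes = [_codes(df[dim]) for dim in fe_dims]
    wsums = [np.bincount(c, weights=w) for c in codes]
    M = df[list(columns)].to_numpy(dtype=float).copy()

    delta = np.inf
    for iteration in range(1, max_iter + 1):
        delta = 0.0
        for c, ws in zip(codes, wsums):
            for j in range(M.shape[1]):
                gmean = np.bincount(c, weights=w * M[:, j]) / ws
                adj = gmean[c]
                M[:, j] -= adj
                delta = max(delta, float(np.max(np.abs(adj))) if len(adj) else 0.0)
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"within transform did not converge in {max_iter} sweeps (last delta {delta:.3e})")

    out = df.copy()
    out[list(columns)] = M
    info = {"iterations": iteration, "delta": delta, "singletons_dropped": n_dropped}
    return out, info


def fit_wls(y, X: pd.DataFrame, weights) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """Weighted least squares via QR on the sqrt(w)-scaled design.

    Returns (coefficients, residuals on the original scale, bread matrix
    (X'WX)^-1). Rank deficiency raises ``CollinearityError`` naming the
    dependent columns found by pivoted QR.
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    sw = np.sqrt(w)
    Xw = Xv * sw[:, None]
    scale = np.linalg.norm(Xw, axis=0)
    if (scale == 0).any():
        bad = [X.columns[j] for j in np.nonzero(scale == 0)[0]]
        raise CollinearityError(bad, f"zero columns after demeaning: {bad}")
    R, P = sla.qr(Xw / scale, mode="r", pivoting=True)
    diag = np.abs(np.diag(R))
    rank_tol = max(Xw.shape) * np.finfo(float).eps * diag.max()
    rank = int((diag > rank_tol).sum())
    if rank < Xw.shape[1]:
        bad = [X.columns[j] for j in P[rank:]]
        raise CollinearityError(bad)
    beta, *_ = np.linalg.lstsq(Xw, yv * sw, rcond=None)
    resid = yv - Xv @ beta
    bread = np.linalg.inv(Xw.T @ Xw)
    return pd.Series(beta, index=X.columns), resid, bread


def _cluster_meat(X: np.ndarray, u: np.ndarray, codes: np.ndarray) -> np.ndarray:
    G = codes.max() + 1
    S = np.zeros((G, X.shape[1]))
    np.add.at(S, codes, X * u[:, None])
    return S.T @ S


def twoway_cluster_cov(
    X: pd.DataFrame,
    residuals,
    weights,
    cluster_a,
    cluster_b=None,
    bread: np.ndarray | None = None,
    k_params: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cameron-Gelbach-Miller multiway cluster-robust covariance.

    One-way when ``cluster_b`` is None; otherwise V_a + V_b - V_ab with the
    intersection clustering subtracted. Each term carries the finite-cluster
    correction G/(G-1) * (N-1)/(N-K). A non-PSD combined matrix has its
    negative eigenvalues floored at zero (flagged in the info dict).
    """
    Xv = X.to_numpy(dtype=float)
    u = np.asarray(residuals, dtype=float)
    w = np.asarray(weights, dtype=float)
    n, k = Xv.shape
    k = k_params if k_params is not None else k
    if bread is None:
        Xw = Xv * np.sqrt(w)[:, None]
        bread = np.linalg.inv(Xw.T @ Xw)
    score = w * u  # weighted score: estfun rows are w_i * u_i * x_i

    def one_way(codes):
        G = codes.max() + 1
        if G < 2:
            raise ValueError(
                "cluster dimension has a single cluster; use one-way clustering "
                "on the other dimension instead")
        c = (G / (G - 1)) * ((n - 1) / (n - k))
        return c * bread @ _cluster_meat(Xv, score, codes) @ bread, G

    ca = _codes(cluster_a)
    Va, Ga = one_way(ca)
    info = {"n_clusters": {"a": Ga}, "psd_repaired": False}
    if cluster_b is None:
        V = Va
    else:
        cb = _codes(cluster_b)
        Vb, Gb = one_way(cb)
        inter = ca.astype(np.int64) * (cb.max() + 1) + cb
        Vab, Gab = one_way(_codes(inter))
        V = Va + Vb - Vab
        info["n_clusters"] = {"a": Ga, "b": Gb, "intersection": Gab}
        eigval, eigvec = np.linalg.eigh(V)
        if eigval.min() < 0:
            V = (eigvec * np.maximum(eigval, 0.0)) @ eigvec.T
            info["psd_repaired"] = True
    V = (V + V.T) / 2
    return pd.DataFrame(V, index=X.columns, columns=X.columns), info


def fe_wls(
    df: pd.DataFrame,
    outcome: str,
    x_cols,
    fe_dims=("person_id", "interview_date"),
    weights: str = "weight",
    clusters=("county_id", "interview_date"),
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ModelFit:
    """Demean -> WLS -> clustered covariance, dropping absorbed columns.

    Columns whose demeaned weighted standard deviation falls below
    ``ABSORBED_TOL`` (e.g. age or schooling under person + exact-date fixed
    effects) are removed from the design and reported in
    ``absorbed_columns`` rather than tripping the rank check.
    """
    x_cols = list(x_cols)
    work = df[[outcome, *x_cols, *fe_dims, weights, *[c for c in clusters if c not in fe_dims]]]
    work = work.dropna()
    demeaned, info = within_transform(work, [outcome, *x_cols], fe_dims, weights, tol, max_iter)
    w = demeaned[weights].to_numpy(dtype=float)

    keep, absorbed = [], []
    for col in x_cols:
        v = demeaned[col].to_numpy()
        sd = np.sqrt(np.average(v ** 2, weights=w))
        (keep if sd > ABSORBED_TOL else absorbed).append(col)
    if absorbed:
        warnings.warn(f"columns absorbed by the fixed effects, dropped: {absorbed}",
                      stacklevel=2)
    if not keep:
        raise CollinearityError(x_cols, "every design column was absorbed by the fixed effects")

    X = demeaned[keep]
    params, resid, bread = fit_wls(demeaned[outcome], X, w)
    ca, cb = (demeaned[clusters[0]], demeaned[clusters[1]] if len(clusters) > 1 else None)
    cov, cov_info = twoway_cluster_cov(X, resid, w, ca, cb, bread=bread)
    names = list(clusters)
    n_clusters = {names[i]: int(g) for i, g in enumerate(cov_info["n_clusters"].values())
                  if i < len(names)}
    df_inf = max(min(n_clusters.values()) - 1, 1)
    return ModelFit(
        params=params,
        cov=cov,
        n_obs=len(demeaned),
        n_clusters=n_clusters,
        residuals=resid,
        term_columns=[],
        fe_iterations=info["iterations"],
        fe_delta=info["delta"],
        singletons_dropped=info["singletons_dropped"],
        absorbed_columns=absorbed,
        psd_repaired=cov_info["psd_repaired"],
        df_inference=df_inf,
    )


def _design_frame(panel, exposures, anomaly_set, spec: ModelSpec) -> tuple[pd.DataFrame, list]:
    term_cols = spec.term_columns()
    pieces = [panel]
    if exposures is not None:
        pieces.append(exposures)
    if anomaly_set is not None:
        overlap = [c for c in anomaly_set.columns if c not in panel.columns]
        pieces.append(anomaly_set[overlap])
    df = pd.concat(pieces, axis=1)
    missing = [c for c in term_cols if c not in df.columns]
    if missing:
        raise ValueError(f"term columns not available: {missing}")
    x_cols = list(term_cols)
    x_cols += [c for c in spec.individual_controls if c in df.columns]
    for c in spec.weather_controls:
        if c in df.columns:
            x_cols.append(c)
            for p in range(2, spec.weather_poly_order + 1):
                name = f"{c}_p{p}"
                df[name] = df[c] ** p
                x_cols.append(name)
    return df, x_cols


def fit_model(panel: pd.DataFrame, exposures: pd.DataFrame | None,
              anomaly_set: pd.DataFrame | None, spec: ModelSpec) -> ModelFit:
    """Fit one specification of the anomaly-well-being model.

    ``panel`` supplies the outcome, controls, weights and cluster keys;
    ``exposures`` the weather-control window means (and bin counts for the
    bins term); ``anomaly_set`` the anomaly columns. All three must share
    the panel's row index. For the bins term coefficients are per-day
    effects relative to the omitted comfortable bin.
    """
    df, x_cols = _design_frame(panel, exposures, anomaly_set, spec)
    fit = fe_wls(df, spec.outcome, x_cols, spec.fixed_effects, spec.weights, spec.clusters)
    fit.term_columns = [c for c in spec.term_columns() if c in fit.params.index]
    return fit


def stratified_fit(panel, exposures, anomaly_set, spec: ModelSpec, grouping,
                   series_map=None, climate_years: int = 50) -> dict:
    """Independent fits of a shared spec per group.

    ``grouping`` is ``"wave"``, ``"climate_quartile"`` (counties binned by
    their mean temperature over the last ``climate_years`` years of the
    weather record -- requires ``series_map``), a panel column name, or an
    explicit label Series aligned with the panel. Groups too small to
    identify the fixed effects are skipped with a warning.
    """
    if isinstance(grouping, str) and grouping == "climate_quartile":
        if series_map is None:
            raise ValueError("climate_quartile grouping needs series_map")
        import datetime as dt

        means = {}
        for cid, s in series_map.items():
            first = max(s.start, dt.date(s.end.year - climate_years + 1, 1, 1))
            i0 = first.toordinal() - s.start.toordinal()
            means[cid] = np.nanmean(s._values["temp"][i0:])
        county_mean = pd.Series(means)
        quart = pd.qcut(county_mean, 4, labels=["q1", "q2", "q3", "q4"])
        labels = panel["county_id"].map(quart)
    elif isinstance(grouping, str):
        labels = panel[grouping]
    else:
        labels = pd.Series(grouping, index=panel.index)

    fits = {}
    for g in labels.dropna().unique():
        mask = (labels == g).to_numpy()
        try:
            fits[g] = fit_model(
                panel.loc[mask],
                exposures.loc[mask] if exposures is not None else None,
                anomaly_set.loc[mask] if anomaly_set is not None else None,
                spec,
            )
        except (CollinearityError, ConvergenceError, ValueError) as exc:
            warnings.warn(f"group {g!r} skipped: {exc}", stacklevel=2)
    return fits


def reference_sweep(panel, series_map, spec: ModelSpec, scheme_grid,
                    exposures: pd.DataFrame | None = None,
                    scheme: str = "preceding_years") -> pd.DataFrame:
    """Refit the model under a grid of reference constructions.

    ``scheme_grid`` holds n values (``preceding_years``) or max ages
    (``cumulative_age``). Each row reports the temperature coefficient, its
    clustered SE, and the sample-average years-missed rate of that
    construction against respondents' true lifetimes.
    """
    if scheme not in {"preceding_years", "cumulative_age"}:
        raise ValueError("scheme_grid sweeps preceding_years or cumulative_age")
    ages = panel["age"].to_numpy()
    rows = []
    for g in scheme_grid:
        if scheme == "preceding_years":
            ref = ReferenceSpec("preceding_years", preceding_years=int(g),
                                window_days=spec.reference.window_days)
            eff_n = np.full_like(ages, int(g))
        else:
            ref = ReferenceSpec("cumulative_age", cumulative_max_age=int(g),
                                window_days=spec.reference.window_days)
            eff_n = np.minimum(ages, int(g))
        anoms = build_anomaly_set(panel, series_map, ref)
        fit = fit_model(panel, exposures, anoms, ModelSpec(
            outcome=spec.outcome, term="anomaly", reference=ref,
            fixed_effects=spec.fixed_effects,
            individual_controls=spec.individual_controls,
            weather_controls=spec.weather_controls if exposures is not None else (),
            weights=spec.weights, clusters=spec.clusters))
        missed = float(np.mean([years_missed_rate(int(a), int(m)) for a, m in zip(ages, eff_n)]))
        ci = fit.conf_int().loc["anomaly"]
        rows.append({
            "scheme": scheme, "param": int(g),
            "beta": float(fit.params["anomaly"]), "se": float(fit.se["anomaly"]),
            "pvalue": float(fit.pvalues["anomaly"]),
            "ci_lower": float(ci["lower"]), "ci_upper": float(ci["upper"]),
            "mean_years_missed": missed, "n_obs": fit.n_obs,
        })
    return pd.DataFrame(rows)
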