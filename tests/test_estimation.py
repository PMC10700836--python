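import warnings

import numpy as np
import pandas as pd
import pytest

import acclimate.synthetic_data as sd
from acclimate.anomalies import ReferenceSpec, build_anomaly_set
from acclimate.errors import CollinearityError, ConvergenceError
from acclimate.estimation import (
    ModelSpec,
    fe_wls,
    fit_model,
    fit_wls,
    reference_sweep,
    stratified_fit,
    twoway_cluster_cov,
    within_transform,
)


def random_panel_instance(seed, n_persons=25, n_dates=10, reps=4):
    """A small two-way panel with weights and a y linear in two covariates
    plus both fixed effects plus noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_persons):
        for d in rng.choice(n_dates, size=reps, replace=False):
            rows.append((p, d))
    df = pd.DataFrame(rows, columns=["person_id", "interview_date"])
    n = len(df)
    fe_p = rng.normal(0, 1, n_persons)
    fe_d = rng.normal(0, 1, n_dates)
    df["x1"] = rng.normal(0, 1, n) + 0.5 * fe_p[df.person_id]
    df["x2"] = rng.normal(0, 1, n) - 0.3 * fe_d[df.interview_date]
    df["weight"] = np.exp(rng.normal(0, 0.3, n))
    df["y"] = (1.5 * df.x1 - 2.0 * df.x2 + fe_p[df.person_id]
               + fe_d[df.interview_date] + rng.normal(0, 0.5, n))
    df["county_id"] = df["person_id"] % 6
    return df


def dummy_ols_coefs(df, y, x_cols, fe_dims, weight_col):
    """Independent oracle: weighted OLS with explicit fixed-effect dummies."""
    dummies = pd.get_dummies(df[list(fe_dims)].astype(str), dtype=float)
    X = pd.concat([df[x_cols].reset_index(drop=True),
                   dummies.reset_index(drop=True)], axis=1)
    sw = np.sqrt(df[weight_col].to_numpy())
    beta, *_ = np.linalg.lstsq(X.to_numpy() * sw[:, None],
                               df[y].to_numpy() * sw, rcond=None)
    return dict(zip(x_cols, beta[: len(x_cols)]))


class TestWithinTransform:
    def test_single_dimension_one_pass_zeroes_group_means(self):
        df = random_panel_instance(0)
        out, info = within_transform(df, ["y", "x1"], fe_dims=("person_id",))
        gm = out.groupby("person_id").apply(
            lambda g: np.average(g["x1"], weights=g["weight"]), include_groups=False)
        assert np.allclose(gm, 0.0, atol=1e-12)
        assert info["iterations"] <= 2

    def test_balanced_layout_converges_in_two_sweeps(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame([(p, d) for p in range(8) for d in range(5)],
                          columns=["person_id", "interview_date"])
        df["x1"] = rng.normal(size=len(df))
        df["y"] = rng.normal(size=len(df))
        df["weight"] = 1.0
        _, info = within_transform(df, ["y", "x1"])
        assert info["iterations"] <= 2

    def test_non_convergence_raises(self):
        df = random_panel_instance(2)
        with pytest.raises(ConvergenceError):
            within_transform(df, ["y", "x1"], max_iter=1, tol=1e-14)

    def test_singletons_dropped_and_counted(self):
        df = random_panel_instance(3).iloc[: 41]  # last person appears once
        out, info = within_transform(df, ["y"], fe_dims=("person_id",))
        assert info["singletons_dropped"] >= 1
        assert (out.groupby("person_id").size() > 1).all()


class TestFitWLS:
    def test_equal_weights_match_ols(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.normal(size=50)
        b1, _, _ = fit_wls(y, X, np.full(50, 2.5))
        b2, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        assert np.allclose(b1, b2, atol=1e-10)

    def test_exact_linear_outcome_zero_residuals(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X @ [2.0, -1.0]
        _, resid, _ = fit_wls(y, X, np.exp(rng.normal(size=40)))
        assert np.max(np.abs(resid)) < 1e-10

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        y = rng.normal(size=30)
        w = np.exp(rng.normal(size=30))
        b, _, _ = fit_wls(y, X, w)
        W = np.diag(w)
        oracle = np.linalg.pinv(X.T @ W @ X) @ (X.T @ W @ y)
        assert np.allclose(b, oracle, atol=1e-9)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["twice_a"] = 2 * X["a"]
        with pytest.raises(CollinearityError) as exc:
            fit_wls(rng.normal(size=30), X, np.ones(30))
        assert "twice_a" in exc.value.columns or "a" in exc.value.columns

    def test_nonpositive_weights_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_wls([1.0, 2.0, 3.0], X, np.array([1.0, 0.0, 1.0]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_demeaned_wls_equals_dummy_variable_ols(self, seed):
        df = random_panel_instance(seed)
        assert len(df) <= 200
        fit = fe_wls(df, "y", ["x1", "x2"], clusters=("county_id", "interview_date"))
        oracle = dummy_ols_coefs(df, "y", ["x1", "x2"],
                                 ("person_id", "interview_date"), "weight")
        for c in ("x1", "x2"):
            assert fit.params[c] == pytest.approx(oracle[c], abs=1e-8)

    def test_fe_constant_column_leaves_slopes_unchanged(self):
        """Frisch-Waugh: a column constant within a fixed-effect group is
        absorbed and must not move the temperature-term slope."""
        df = random_panel_instance(13)
        df["person_trait"] = df["person_id"] * 3.7  # constant within person
        base = fe_wls(df, "y", ["x1", "x2"], clusters=("county_id", "interview_date"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aug = fe_wls(df, "y", ["x1", "x2", "person_trait"],
                         clusters=("county_id", "interview_date"))
        assert "person_trait" in aug.absorbed_columns
        assert np.allclose(base.params[["x1", "x2"]], aug.params[["x1", "x2"]], atol=1e-9)


class TestClusterCovariance:
    @staticmethod
    def _instance(seed=3, n=60):
        rng = np.random.default_rng(seed)
        ca = np.repeat(np.arange(10), n // 10)
        cb = np.tile(np.arange(6), n // 6)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        X.insert(0, "const", 1.0)
        u = rng.normal(size=10)[ca] + rng.normal(size=6)[cb] + rng.normal(size=n)
        y = X["a"] - 2 * X["b"] + u
        w = np.exp(rng.normal(0, 0.3, n))
        return X, y, w, ca, cb

    def test_all_singleton_clusters_reduce_to_hc1(self):
        import statsmodels.api as sm

        X, y, w, _, _ = self._instance()
        params, resid, bread = fit_wls(y, X, w)
        V, _ = twoway_cluster_cov(X, resid, w, np.arange(len(y)), None, bread=bread)
        hc1 = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
        assert np.allclose(V.to_numpy(), hc1.cov_params(), rtol=1e-8)

    def test_distinct_second_dimension_cancels_to_one_way(self):
        X, y, w, ca, _ = self._instance()
        _, resid, bread = fit_wls(y, X, w)
        V1, _ = twoway_cluster_cov(X, resid, w, ca, None, bread=bread)
        V2, info = twoway_cluster_cov(X, resid, w, ca, np.arange(len(y)), bread=bread)
        assert np.allclose(V1.to_numpy(), V2.to_numpy(), atol=1e-12)

    def test_matches_reference_implementation_on_60_rows(self):
        import statsmodels.api as sm
        import statsmodels.stats.sandwich_covariance as sw

        X, y, w, ca, cb = self._instance()
        _, resid, bread = fit_wls(y, X, w)
        V, info = twoway_cluster_cov(X, resid, w, ca, cb, bread=bread)
        res = sm.WLS(y, X, weights=w).fit()
        one_way = res.get_robustcov_results(cov_type="cluster", groups=ca).cov_params()
        Va, _ = twoway_cluster_cov(X, resid, w, ca, None, bread=bread)
        assert np.allclose(Va.to_numpy(), one_way, rtol=1e-6)
        expected, _, _ = sw.cov_cluster_2groups(res, ca, cb)
        assert not info["psd_repaired"]
        assert np.allclose(V.to_numpy(), expected, rtol=1e-6)

    def test_psd_repair_floors_negative_eigenvalues(self):
        rng = np.random.default_rng(3)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 4)))
        y = rng.normal(size=n)
        w = np.ones(n)
        _, resid, bread = fit_wls(y, X, w)
        V, info = twoway_cluster_cov(X, resid, w, rng.integers(0, 8, n),
                                     rng.integers(0, 6, n), bread=bread)
        assert np.linalg.eigvalsh(V.to_numpy()).min() >= -1e-12

    def test_single_cluster_dimension_rejected(self):
        X, y, w, ca, _ = self._instance()
        _, resid, bread = fit_wls(y, X, w)
        with pytest.raises(ValueError, match="one-way"):
            twoway_cluster_cov(X, resid, w, np.zeros(len(y), dtype=int), ca, bread=bread)


class TestFitModel:
    def test_age_and_schooling_absorbed_by_fixed_effects(self, small_world, small_panel):
        _, _, smap = small_world
        anoms = build_anomaly_set(small_panel, smap, ReferenceSpec())
        panel = sd.simulate_swb(small_panel, anoms["anomaly"].to_numpy(),
                                sd.DGPParams(), seed=1)
        with pytest.warns(UserWarning, match="absorbed"):
            fit = fit_model(panel, None, anoms, ModelSpec(weather_controls=()))
        assert "age" in fit.absorbed_columns
        assert "education" in fit.absorbed_columns
        assert fit.term_columns == ["anomaly"]
        assert np.allclose(np.sqrt(np.diag(fit.cov.to_numpy())), fit.se)

    def test_strong_signal_recovery(self, small_world, small_panel):
        _, _, smap = small_world
        anoms = build_anomaly_set(small_panel, smap, ReferenceSpec())
        dgp = sd.DGPParams(beta_true=-0.5, noise_sd=0.2)
        panel = sd.simulate_swb(small_panel, anoms["anomaly"].to_numpy(), dgp, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(panel, None, anoms, ModelSpec(weather_controls=()))
        assert fit.params["anomaly"] == pytest.approx(-0.5, abs=3 * fit.se["anomaly"])

    def test_split_dgp_zero_negative_coefficient(self, study_world):
        """When only hotter-than-expected anomalies enter the outcome, the
        colder-than-expected coefficient estimates a true zero."""
        _, co, smap = study_world
        panel = sd.simulate_panel(co, n_individuals=1500, seed=77)
        anoms = build_anomaly_set(panel, smap, ReferenceSpec())
        dgp = sd.DGPParams(beta_true=-0.4, noise_sd=0.3)
        panel = sd.simulate_swb(panel, anoms["positive_part"].to_numpy(), dgp, seed=78)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(panel, None, anoms, ModelSpec(term="split", weather_controls=()))
        assert fit.params["positive_part"] == pytest.approx(-0.4, abs=3 * fit.se["positive_part"])
        assert abs(fit.params["negative_part"]) < 3 * fit.se["negative_part"]

    def test_bins_flat_response_all_near_zero(self, study_world):
        from acclimate.weather import BinSpec, build_exposures

        _, co, smap = study_world
        rng = np.random.default_rng(9)
        panel = sd.simulate_panel(co, n_individuals=600, seed=90)
        panel["swb"] = 3.0 + rng.normal(0, 0.1, len(panel))
        expo = build_exposures(panel, smap, bin_spec=BinSpec())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(panel, expo, None, ModelSpec(
                term="bins", individual_controls=(), weather_controls=(),
                fixed_effects=("county_id", "interview_date")))
        assert "bin_18_21" not in fit.params.index  # omitted comfortable bin
        for c in fit.term_columns:
            assert abs(fit.params[c]) < 4 * fit.se[c] + 0.05


class TestStratifiedFit:
    def test_one_group_identical_to_pooled(self, small_world, small_panel):
        _, _, smap = small_world
        anoms = build_anomaly_set(small_panel, smap, ReferenceSpec())
        panel = sd.simulate_swb(small_panel, anoms["anomaly"].to_numpy(),
                                sd.DGPParams(), seed=3)
        spec = ModelSpec(weather_controls=(), individual_controls=())
        pooled = fit_model(panel, None, anoms, spec)
        fits = stratified_fit(panel, None, anoms, spec,
                              pd.Series("all", index=panel.index))
        assert np.allclose(fits["all"].params, pooled.params, atol=1e-12)

    def test_wave_grouping_yields_three_fits(self, study_world):
        _, co, smap = study_world
        panel = sd.simulate_panel(co, n_individuals=800, seed=55)
        anoms = build_anomaly_set(panel, smap, ReferenceSpec())
        panel = sd.simulate_swb(panel, anoms["anomaly"].to_numpy(), sd.DGPParams(), seed=56)
        spec = ModelSpec(weather_controls=(), individual_controls=(),
                         fixed_effects=("county_id", "interview_date"))
        fits = stratified_fit(panel, None, anoms, spec, "wave")
        assert sorted(fits) == [2010, 2014, 2018]

    def test_recovers_regionally_varying_response(self, study_world):
        _, co, smap = study_world
        rng = np.random.default_rng(60)
        panel = sd.simulate_panel(co, n_individuals=1200, seed=60)
        anoms = build_anomaly_set(panel, smap, ReferenceSpec())
        region = panel["county_id"].map(co.set_index("county_id")["region_id"])
        beta_by_region = {0: -0.1, 1: -0.4, 2: -0.8, 3: -1.2}
        panel["swb"] = (region.map(beta_by_region).to_numpy() * anoms["anomaly"].to_numpy()
                        + rng.normal(0, 0.3, len(panel)))
        spec = ModelSpec(weather_controls=(), individual_controls=(),
                         fixed_effects=("county_id", "interview_date"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = stratified_fit(panel, None, anoms, spec, region)
        got = [float(fits[r].params["anomaly"]) for r in sorted(fits)]
        assert all(a > b for a, b in zip(got, got[1:]))  # imposed gradient ordering


class TestReferenceSweep:
    @staticmethod
    def _uniform_age_panel(study_world, birth_year, n=400, seed=70):
        _, co, smap = study_world
        panel = sd.simulate_panel(co, waves=[2014], n_individuals=n,
                                  birth_year_range=(birth_year, birth_year), seed=seed)
        anoms = build_anomaly_set(panel, smap, ReferenceSpec())
        panel = sd.simulate_swb(panel, anoms["anomaly"].to_numpy(),
                                sd.DGPParams(noise_sd=0.3), seed=seed + 1)
        return panel, smap, anoms

    def test_age_matched_n_reproduces_lifetime_fit(self, study_world):
        panel, smap, anoms = self._uniform_age_panel(study_world, 1989)
        spec = ModelSpec(weather_controls=(), individual_controls=(),
                         fixed_effects=("county_id", "interview_date"))
        base = fit_model(panel, None, anoms, spec)
        sweep = reference_sweep(panel, smap, spec, [25])
        assert sweep.loc[0, "beta"] == pytest.approx(
            float(base.params["anomaly"]), abs=1e-10)
        assert sweep.loc[0, "mean_years_missed"] == 0.0

    def test_years_missed_column_for_age_50_at_n_25(self, study_world):
        panel, smap, _ = self._uniform_age_panel(study_world, 1964)
        spec = ModelSpec(weather_controls=(), individual_controls=(),
                         fixed_effects=("county_id", "interview_date"))
        sweep = reference_sweep(panel, smap, spec, [25])
        assert sweep.loc[0, "mean_years_missed"] == pytest.approx(0.50)

    def test_one_row_per_grid_point_with_cis(self, study_world):
        panel, smap, _ = self._uniform_age_panel(study_world, 1980)
        spec = ModelSpec(weather_controls=(), individual_controls=(),
                         fixed_effects=("county_id", "interview_date"))
        sweep = reference_sweep(panel, smap, spec, [5, 15, 30])
        assert list(sweep["param"]) == [5, 15, 30]
        assert (sweep["ci_lower"] <= sweep["beta"]).all()
        assert (sweep["beta"] <= sweep["ci_upper"]).all()
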