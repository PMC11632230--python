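import copy

import numpy as np
import pandas as pd
import pytest

from frailtyburst import (
    CohortDesign,
    DEFAULT_GENERATING_PARAMS,
    LocationScaleMixedRegression,
    compare_models,
    posterior_predictive_mean_isd,
    simulate_cohort,
    variance_decomposition,
)


def homoscedastic_params(sigma=0.05):
    """Constant-dispersion generating values.

    The mean is centred at 0.5, far from the [0, 1] bounds: boundary
    truncation would otherwise induce genuine location-dependent dispersion
    and the data would not actually be homoscedastic.
    """
    params = copy.deepcopy(DEFAULT_GENERATING_PARAMS)
    params["beta"] = {k: 0.0 for k in params["beta"]}
    params["beta"]["intercept"] = 0.5
    params["beta"]["burst2"] = 0.01
    params["gamma"] = {k: 0.0 for k in params["gamma"]}
    params["gamma"]["intercept"] = float(np.log(sigma))
    params["sds"]["sd_person_sc"] = 1e-6
    params["sds"]["sd_burst_sc"] = 1e-6
    params["sds"]["sd_burst_wave"] = 1e-6
    params["cors"] = {k: 0.0 for k in params["cors"]}
    return params


@pytest.fixture(scope="module")
def homoscedastic_cohort():
    design = CohortDesign(
        n_persons=70, render_deficits=False, params=homoscedastic_params()
    )
    frame, truth = simulate_cohort(design, seed=31)
    return frame, truth


@pytest.fixture(scope="module")
def m2_fit(fi_cohort):
    frame, _ = fi_cohort
    return LocationScaleMixedRegression(model="M2", seed=3, draws=400).fit(frame)


class TestFitContract:
    def test_same_seed_identical_summaries(self, fi_cohort):
        frame, _ = fi_cohort
        fits = [
            LocationScaleMixedRegression(model="M2", seed=5, draws=100).fit(frame)
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(fits[0].location_coefs_, fits[1].location_coefs_)
        pd.testing.assert_frame_equal(fits[0].scale_coefs_, fits[1].scale_coefs_)
        assert fits[0].loglik_ == fits[1].loglik_

    def test_exponentiation_consistency(self, m2_fit):
        # the log of every reported sigma coefficient is the raw coefficient
        np.testing.assert_allclose(
            np.log(m2_fit.scale_coefs_["estimate"]),
            m2_fit.scale_coefs_["log_estimate"],
            atol=1e-12,
        )

    def test_interval_order_and_domains(self, m2_fit):
        for tbl in (m2_fit.location_coefs_, m2_fit.scale_coefs_, m2_fit.random_sd_):
            assert (tbl["ci_low"] <= tbl["ci_high"]).all()
        assert (m2_fit.scale_coefs_["estimate"] > 0).all()
        assert (m2_fit.random_sd_["estimate"] >= 0).all()
        cors = m2_fit.random_cor_["estimate"]
        assert ((cors >= -1) & (cors <= 1)).all()

    def test_invalid_engine_rejected(self, fi_cohort):
        frame, _ = fi_cohort
        with pytest.raises(ValueError, match="engine"):
            LocationScaleMixedRegression(engine="vb").fit(frame)


class TestLMMLimit:
    def test_homoscedastic_m2_scale_effects_shrink(self, homoscedastic_cohort, m2_fit):
        # with no generating scale heterogeneity the scale random SDs collapse
        # to a small fraction of their heteroscedastic counterparts
        frame, _ = homoscedastic_cohort
        est = LocationScaleMixedRegression(
            model="M2", seed=0, compute_uncertainty=False
        ).fit(frame)
        tau_a = est.random_sd_.loc["sd_person_sc", "estimate"]
        assert tau_a < 0.15
        assert tau_a < 0.5 * m2_fit.random_sd_.loc["sd_person_sc", "estimate"]
        assert est.random_sd_.loc["sd_burst_sc", "estimate"] < 0.15
        # residual SD at reference recovers the generating sigma
        assert est.scale_coefs_.loc["intercept", "estimate"] == pytest.approx(0.05, rel=0.1)

    def test_location_coefficients_match_mixedlm_oracle(self, homoscedastic_cohort):
        import statsmodels.formula.api as smf

        frame, _ = homoscedastic_cohort
        est = LocationScaleMixedRegression(
            model="M2", seed=0, compute_uncertainty=False
        ).fit(frame)
        df = frame[frame["fi"].notna()].copy()
        df["wave_c"] = df["wave"] - 4.0
        df["burst2"] = (df["burst"] == 2).astype(float)
        df["pb"] = df["person_id"].astype(str) + ":" + df["burst"].astype(str)
        md = smf.mixedlm(
            "fi ~ wave_c + burst2",
            df,
            groups="person_id",
            re_formula="1",
            vc_formula={"burst": "0 + C(pb)"},
        )
        lmm = md.fit(reml=False)
        ours = est.location_coefs_["estimate"]
        assert ours["intercept"] == pytest.approx(lmm.params["Intercept"], abs=0.01)
        assert ours["wave"] == pytest.approx(lmm.params["wave_c"], abs=0.005)
        assert ours["burst2"] == pytest.approx(lmm.params["burst2"], abs=0.01)
        # person-level SD agrees with the LMM random-intercept SD
        sd_lmm = float(np.sqrt(lmm.cov_re.iloc[0, 0]))
        assert est.random_sd_.loc["sd_person_loc", "estimate"] == pytest.approx(
            sd_lmm, rel=0.15
        )


class TestVarianceDecomposition:
    def test_equal_components(self):
        out = variance_decomposition(1.0, 1.0, 1.0)
        for key in ("between_person_pct", "between_burst_pct", "within_burst_pct"):
            assert out[key] == pytest.approx(100 / 3)

    def test_degenerate_components(self):
        out = variance_decomposition(2.5, 0.0, 0.0)
        assert out["between_person_pct"] == 100.0

    def test_study_ratio_recovered_exactly(self):
        out = variance_decomposition(77.3, 9.8, 12.9)
        assert out["between_person_pct"] == pytest.approx(77.3)
        assert out["between_burst_pct"] == pytest.approx(9.8)
        assert out["within_burst_pct"] == pytest.approx(12.9)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.uniform(0.001, 5.0, size=3)
            out = variance_decomposition(*v)
            total = (
                out["between_person_pct"]
                + out["between_burst_pct"]
                + out["within_burst_pct"]
            )
            assert total == pytest.approx(100.0)

    def test_m0_fit_decomposes(self, fi_cohort):
        frame, _ = fi_cohort
        m0 = LocationScaleMixedRegression(
            model="M0", seed=0, compute_uncertainty=False
        ).fit(frame)
        out = m0.decompose_variance()
        assert out["between_person_pct"] > 50  # stable differences dominate
        total = (
            out["between_person_pct"] + out["between_burst_pct"] + out["within_burst_pct"]
        )
        assert total == pytest.approx(100.0)

    def test_non_m0_fit_rejected(self, m2_fit):
        with pytest.raises(ValueError, match="M0"):
            m2_fit.decompose_variance()


class TestBayesR2:
    def test_intercept_only_location_near_zero(self, fi_cohort):
        frame, _ = fi_cohort
        m0 = LocationScaleMixedRegression(model="M0", seed=0, draws=200).fit(frame)
        assert m0.bayes_r2() == pytest.approx(0.0, abs=1e-6)

    def test_strong_predictor_drives_r2_to_one(self):
        params = homoscedastic_params(sigma=0.002)
        params["beta"] = {k: 0.0 for k in params["beta"]}
        params["beta"]["intercept"] = 0.3
        params["beta"]["age_c"] = 0.02  # dominant continuous predictor
        params["sds"]["sd_person_loc"] = 1e-3
        params["sds"]["sd_burst_loc"] = 1e-3
        design = CohortDesign(n_persons=60, render_deficits=False, params=params)
        frame, _ = simulate_cohort(design, seed=13)
        est = LocationScaleMixedRegression(model="M3", seed=0, draws=200).fit(frame)
        assert est.bayes_r2() > 0.9


class TestReportTable:
    def test_csv_round_trip(self, m2_fit):
        import io

        table = m2_fit.report_table(fmt="frame")
        back = pd.read_csv(io.StringIO(m2_fit.report_table(fmt="csv")))
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_markdown_and_csv_agree(self, m2_fit):
        md = m2_fit.report_table(fmt="markdown")
        table = m2_fit.report_table(fmt="frame")
        for val in table["mu"].dropna():
            assert f"{val:.2f}" in md

    def test_location_only_fit_suppresses_sigma_column(self, fi_cohort):
        frame, _ = fi_cohort
        m1 = LocationScaleMixedRegression(
            model="M1", seed=0, compute_uncertainty=False, draws=50
        ).fit(frame)
        table = m1.report_table(fmt="frame")
        assert "sigma" not in table.columns


class TestModelComparison:
    def test_identical_fits_have_zero_difference(self, fi_cohort):
        frame, _ = fi_cohort
        a = LocationScaleMixedRegression(model="M1", seed=7, draws=100).fit(frame)
        b = LocationScaleMixedRegression(model="M1", seed=7, draws=100).fit(frame)
        out = compare_models(a, b, n_draws=50)
        assert out["elpd_diff"] == pytest.approx(0.0, abs=1e-6)
        assert out["preferred"] is None

    def test_mismatched_data_rejected(self, fi_cohort, homoscedastic_cohort):
        a = LocationScaleMixedRegression(model="M1", seed=0, draws=50).fit(fi_cohort[0])
        b = LocationScaleMixedRegression(model="M1", seed=0, draws=50).fit(
            homoscedastic_cohort[0]
        )
        with pytest.raises(ValueError, match="identical data"):
            compare_models(a, b)


class TestMcmcEngine:
    def test_small_model_runs_and_is_deterministic(self, fi_cohort):
        frame, _ = fi_cohort
        kwargs = dict(model="M0", engine="mcmc", seed=4, draws=100, mcmc_steps=120)
        a = LocationScaleMixedRegression(**kwargs).fit(frame)
        b = LocationScaleMixedRegression(**kwargs).fit(frame)
        assert hasattr(a, "rhat_max_") and hasattr(a, "ess_min_")
        pd.testing.assert_frame_equal(a.location_coefs_, b.location_coefs_)
        # short chains flag their own diagnostics honestly
        assert isinstance(a.warnings_, list)


def test_posterior_predictive_isd_self_consistency(m2_fit):
    out = posterior_predictive_mean_isd(m2_fit, n_rep=200, seed=1)
    assert out["ci_low"] <= out["observed"] <= out["ci_high"]
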