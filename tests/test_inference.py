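"""Site-mean OLS, crossed mixed model, bias statistic, partial residuals."""

import numpy as np
import pandas as pd
import pytest

import leafopt
from leafopt.inference import (
    CLIMATE_PREDICTORS,
    CollinearityError,
    RegressionSpec,
    bias,
    bias_regression,
    cooks_distance,
    fit_all_species,
    fit_site_mean,
    leaf_soil_regressions,
    partial_residuals,
    refit_without_influential,
    theoretical_prediction,
)
from leafopt.synth import GeneratorConfig, generate


def _linear_site_table(n=60, coefs=(2.0, 1.0, -0.05, 0.07), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ppfd = np.exp(rng.uniform(np.log(100), np.log(800), n))
    tg = rng.uniform(0, 30, n)
    d = np.exp(rng.uniform(np.log(0.1), np.log(3), n))
    lnv = (coefs[0] + coefs[1] * np.log(ppfd) + coefs[2] * tg
           + coefs[3] * np.log(d) + noise * rng.normal(size=n))
    return pd.DataFrame({"vcmax25": np.exp(lnv), "ppfd": ppfd, "tg_c": tg,
                         "d_kpa": d})


class TestSiteMeanOLS:
    def test_noise_free_exact_recovery(self):
        fit = fit_site_mean(_linear_site_table())
        np.testing.assert_allclose(
            fit.params[["const", "ln_ppfd", "tg_c", "ln_d_kpa"]],
            [2.0, 1.0, -0.05, 0.07], atol=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_sample_size_rejected(self):
        with pytest.raises(ValueError, match="need n >"):
            fit_site_mean(_linear_site_table(n=4))

    def test_collinear_design_names_offender(self):
        df = _linear_site_table(n=30)
        df["tg_c"] = 17.0  # constant column duplicates the intercept
        with pytest.raises(CollinearityError, match="tg_c"):
            fit_site_mean(df)

    def test_row_order_invariance(self):
        df = _linear_site_table(n=40, noise=0.3)
        a = fit_site_mean(df)
        b = fit_site_mean(df.sample(frac=1.0, random_state=9))
        np.testing.assert_allclose(a.params, b.params, rtol=1e-10)

    def test_affine_rescaling_rescales_coefficient(self):
        df = _linear_site_table(n=40, noise=0.3)
        a = fit_site_mean(df, RegressionSpec("vcmax25", True, (("tg_c", False),)))
        df2 = df.assign(tg_c=2.0 * df["tg_c"])
        b = fit_site_mean(df2, RegressionSpec("vcmax25", True, (("tg_c", False),)))
        assert b.params["tg_c"] == pytest.approx(a.params["tg_c"] / 2.0, rel=1e-10)


class TestMixedModel:
    def test_zero_variance_random_effects_collapse_to_ols(self):
        cfg = GeneratorConfig(n_sites=40, species_range=(4, 6), species_pool=60,
                              sigma_site=0.0, sigma_species=0.0, sigma_resid=0.3)
        rec = generate(cfg, seed=3).records_with_climate()
        mixed = fit_all_species(rec)
        ols = fit_site_mean(rec, RegressionSpec("vcmax25", True, CLIMATE_PREDICTORS))
        for name in ("ln_ppfd", "tg_c", "ln_d_kpa"):
            key = name if name in mixed.params.index else name
            assert mixed.params[key] == pytest.approx(ols.params[name], abs=1e-6)

    def test_shared_species_across_sites_handled(self):
        cfg = GeneratorConfig(n_sites=30, species_range=(6, 8), species_pool=12)
        sim = generate(cfg, seed=4)
        rec = sim.records_with_climate()
        per_site_counts = rec.groupby("species")["site_id"].nunique()
        assert (per_site_counts > 1).any()
        fit = fit_all_species(rec)
        assert fit.n == len(rec)
        assert set(fit.varfrac) == {"site_id", "species", "residual"}
        assert all(0 <= v <= 1 for v in fit.varfrac.values())
        assert sum(fit.varfrac.values()) == pytest.approx(1.0, abs=1e-9)

    def test_adding_true_random_effect_increases_ml_loglik(self):
        cfg = GeneratorConfig(n_sites=50, species_range=(4, 6), species_pool=80)
        rec = generate(cfg, seed=6).records_with_climate()
        mixed = fit_all_species(rec, reml=False)
        import statsmodels.api as sm

        data = mixed.design
        X = sm.add_constant(data[["ln_ppfd", "tg_c", "ln_d_kpa"]])
        ols = sm.OLS(data["_y"], X).fit()
        assert mixed.result.llf > ols.llf


class TestBias:
    @pytest.mark.parametrize("pred,obs,want", [(100.0, 100.0, 0.0),
                                               (110.0, 100.0, 10.0),
                                               (50.0, 100.0, -50.0)])
    def test_trivial_cases(self, pred, obs, want):
        assert bias(pred, obs) == pytest.approx(want)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        p, o = rng.uniform(10, 100, 50), rng.uniform(10, 100, 50)
        np.testing.assert_allclose(bias(3.7 * p, 3.7 * o), bias(p, o), rtol=1e-12)

    def test_nonpositive_observation_rejected(self):
        with pytest.raises(ValueError):
            bias(50.0, 0.0)

    def test_theoretical_prediction_composes_with_bias(self, default_sim):
        sites = default_sim.truth_sites.head(20)
        pred = theoretical_prediction(sites)
        np.testing.assert_allclose(np.log(pred), sites["lnv_theory"], atol=1e-12)
        assert np.all(bias(pred, np.exp(sites["lnv_theory"])) == pytest.approx(0.0))


class TestBiasRegression:
    def test_all_zero_bias_gives_zero_slope(self):
        df = pd.DataFrame({"bias": np.zeros(30),
                           "parea": np.random.default_rng(0).uniform(0.05, 0.3, 30)})
        fit = bias_regression(df, [("parea", False)])
        assert fit.params["parea"] == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_rate(self):
        """Bias independent of the covariate: slope within 2 SE of zero in
        >= 90 % of replicates."""
        rng = np.random.default_rng(101)
        cover = 0
        reps = 100
        for _ in range(reps):
            df = pd.DataFrame({"bias": rng.normal(0, 10, 200),
                               "parea": rng.uniform(0.05, 0.3, 200)})
            fit = bias_regression(df, [("parea", False)])
            if abs(fit.params["parea"]) < 2 * fit.bse["parea"]:
                cover += 1
        assert cover >= 90

    def test_power_against_constructed_signal(self):
        """bias = 0.5 (parea - mean) + noise is detected (p < 0.05) in
        >= 90 % of replicates at n = 200."""
        rng = np.random.default_rng(202)
        hits = 0
        reps = 100
        for _ in range(reps):
            parea = rng.uniform(0.05, 0.3, 200)
            signal = 0.5 * (parea - parea.mean())
            noise = rng.normal(0, 2.0 * signal.std(), 200)
            df = pd.DataFrame({"bias": signal + noise, "parea": parea})
            fit = bias_regression(df, [("parea", False)])
            if fit.params["parea"] > 0 and fit.pvalues["parea"] < 0.05:
                hits += 1
        assert hits >= 90


class TestPartialResiduals:
    def test_single_predictor_model_returns_observations(self):
        df = _linear_site_table(n=25, noise=0.4, seed=3)
        spec = RegressionSpec("vcmax25", True, (("tg_c", False),))
        fit = fit_site_mean(df, spec)
        pr = partial_residuals(fit, "tg_c")
        np.testing.assert_allclose(pr["partial_residual"],
                                   np.log(df["vcmax25"]), atol=1e-10)

    @pytest.mark.parametrize("predictor", ["ln_ppfd", "tg_c", "ln_d_kpa"])
    def test_slope_equals_fitted_coefficient(self, predictor):
        df = _linear_site_table(n=80, noise=0.5, seed=8)
        fit = fit_site_mean(df)
        pr = partial_residuals(fit, predictor)
        slope = np.polyfit(pr["x"], pr["partial_residual"], 1)[0]
        assert slope == pytest.approx(fit.params[predictor], rel=1e-9)

    def test_four_point_hand_example(self):
        # y = [1, 2, 4, 5] on x = [0, 1, 2, 3]: OLS slope 1.4, intercept 0.9
        df = pd.DataFrame({"y": [1.0, 2.0, 4.0, 5.0], "x": [0.0, 1.0, 2.0, 3.0]})
        fit = fit_site_mean(df, RegressionSpec("y", False, (("x", False),)))
        pr = partial_residuals(fit, "x")
        np.testing.assert_allclose(pr["partial_residual"], df["y"], atol=1e-12)

    def test_unknown_predictor(self):
        fit = fit_site_mean(_linear_site_table(n=20))
        with pytest.raises(KeyError):
            partial_residuals(fit, "soil_moisture")


class TestLeafSoil:
    @staticmethod
    def _site_means(cfg, seed):
        sim = generate(cfg, seed=seed)
        return leafopt.aggregate_site_means(
            sim.truth_records.rename(columns={"species": "species"}),
            sim.soil)

    def test_sign_recovery_with_coupled_generator(self):
        """Parea tracks soil P (positive) and Narea tracks pH (negative) by
        construction; the joint OLS recovers both signs in >= 95 % of
        replicates."""
        cfg = GeneratorConfig(narea_ph_slope=-0.25, narea_sd=0.15,
                              parea_sd=0.15)
        ok_p = ok_n = 0
        reps = 20
        for seed in range(reps):
            fits = leaf_soil_regressions(self._site_means(cfg, seed))
            if fits["parea"].params["ln_total_p"] > 0:
                ok_p += 1
            if fits["narea"].params["ph"] < 0:
                ok_n += 1
        assert ok_p >= 0.95 * reps
        assert ok_n >= 0.95 * reps

    def test_type_one_with_decoupled_generator(self):
        cfg = GeneratorConfig(parea_soilp_slope=0.0, narea_ph_slope=0.0)
        within = 0
        reps = 20
        for seed in range(100, 100 + reps):
            fits = leaf_soil_regressions(self._site_means(cfg, seed))
            f = fits["parea"]
            if abs(f.params["ln_total_p"]) < 2 * f.bse["ln_total_p"]:
                within += 1
        assert within >= 0.8 * reps

    def test_constant_soil_column_raises(self, default_sim):
        sm_ = leafopt.aggregate_site_means(default_sim.truth_records,
                                           default_sim.soil)
        sm_["ph"] = 6.0
        with pytest.raises(CollinearityError):
            leaf_soil_regressions(sm_)

    def test_missing_soil_skipped(self):
        df = _linear_site_table(n=20).assign(narea=1.5, parea=0.1)
        fits = leaf_soil_regressions(df)
        assert fits["narea"] is None and fits["parea"] is None


class TestInfluence:
    def test_cooks_distance_and_refit_utility(self):
        df = _linear_site_table(n=50, noise=0.2, seed=13)
        df.loc[0, "vcmax25"] *= 30.0  # one gross outlier
        spec = RegressionSpec("vcmax25", True, CLIMATE_PREDICTORS)
        full = fit_site_mean(df, spec)
        d = cooks_distance(full)
        assert d.idxmax() == 0
        refit, dropped = refit_without_influential(df, spec, k=1)
        assert dropped == [0]
        assert refit.n == full.n - 1
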