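"""Probit mixed-model fitting: aggregation, Laplace accuracy, invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fatiguelag import synthetic as syn
from fatiguelag.glmm import (_build_arrays, _laplace_loglik, choice_table,
                             delay_predictor_table, fit_probit_glmm,
                             model_comparison_aic, slope_correlation)
from oracles import aghq_loglik


class TestChoiceTable:
    def test_counting(self):
        rec = pd.DataFrame({"participant_id": 0, "lag_ms": 50,
                            "comparison_phase": [1] * 5 + [2] * 5,
                            "choice_comparison": [1, 1, 1, 1, 0, 1, 1, 1, 0, 0]})
        tab = choice_table(rec)
        assert tab.loc[0, "n_trials"] == 10
        assert tab.loc[0, "proportion"] == pytest.approx(0.7)

    def test_chance_level_for_balanced_random(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame({"participant_id": 0, "lag_ms": 0,
                            "comparison_phase": rng.integers(1, 3, 40000),
                            "choice_comparison": rng.integers(0, 2, 40000)})
        assert choice_table(rec)["proportion"].iloc[0] == pytest.approx(0.5, abs=0.01)

    def test_phase_pooling_cancels_order_bias(self):
        """A +-delta order bias on the linear predictor vanishes after pooling."""
        cfg = syn.experiment1_config(n_participants=1, blocks=15, seed=21)
        hyper = syn.CohortHyper(alpha=0.0, beta=0.0, order_bias=0.6,
                                sd_alpha_i=0, sd_beta_i=0, sd_det_alpha_i=0,
                                sd_det_beta_i=0, sd_alpha_d_i=0, sd_beta_d_i=0)
        cohort, truth = syn.make_cohort(cfg, hyper, seed=21)
        n = 40000
        table = pd.DataFrame({"participant_id": 0, "lag_ms": [50] * n,
                              "comparison_phase": [1, 2] * (n // 2)})
        rec = syn.simulate_choices(cohort[0], table, truth, "fatigue", seed=21)
        by_phase = rec.groupby("comparison_phase")["choice_comparison"].mean()
        assert abs(by_phase[1] - by_phase[2]) > 0.3     # bias is real per phase
        pooled = choice_table(rec)["proportion"].iloc[0]
        assert pooled == pytest.approx(0.5, abs=0.01)   # and pooling removes it

    def test_extreme_proportions_shrunk(self):
        rec = pd.DataFrame({"participant_id": 0, "lag_ms": [50] * 10,
                            "comparison_phase": 1, "choice_comparison": 1})
        tab = delay_predictor_table(rec)
        assert tab["p_delay"].iloc[0] == pytest.approx(1 - 0.05)


class TestLaplaceAccuracy:
    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_laplace_close_to_quadrature_model1(self, seed):
        """|Laplace - AGHQ(31)| <= 0.1 on small two-random-effect instances."""
        cfg = syn.experiment1_config(n_participants=4, blocks=2, seed=seed)
        cohort, truth = syn.make_cohort(cfg, seed=seed)
        fat = syn.build_dataset(cfg, cohort, truth, seed=seed).query(
            "session == 'fatigue'")
        _, _, _, X, Z, y, n = _build_arrays(fat, 1, None)
        for gamma, sd in [(np.array([0.1, 0.01]), np.array([0.3, 0.004])),
                          (np.array([-0.2, 0.005]), np.array([0.5, 0.01]))]:
            lap, _ = _laplace_loglik(gamma, sd, X, Z, y, n)
            assert lap == pytest.approx(
                aghq_loglik(gamma, sd, X, Z, y, n, n_nodes=31), abs=0.1)

    def test_laplace_close_to_quadrature_at_fitted_optimum(self):
        cfg = syn.experiment1_config(n_participants=5, blocks=2, seed=6)
        cohort, truth = syn.make_cohort(cfg, seed=6)
        data = syn.build_dataset(cfg, cohort, truth, seed=6)
        fat = data[data["session"] == "fatigue"]
        fit = fit_probit_glmm(fat, model_id=1, compute_se=False)
        _, _, _, X, Z, y, n = _build_arrays(fat, 1, None)
        gamma = np.array([fit.fixed_effects["alpha"], fit.fixed_effects["beta"]])
        sd = np.array([max(fit.re_sd["sd_alpha_i"], 1e-6),
                       max(fit.re_sd["sd_beta_i"], 1e-6)])
        assert fit.loglik == pytest.approx(
            aghq_loglik(gamma, sd, X, Z, y, n, n_nodes=31), abs=0.1)

    def test_zero_variance_matches_plain_probit(self):
        """In the vanishing-variance limit the GLMM is an ordinary probit.

        On finite data the free ML variance estimate fluctuates above zero,
        so the degeneracy is tested with the variance components profiled
        at (effectively) zero.
        """
        cfg = syn.experiment1_config(n_participants=8, blocks=15, seed=7)
        hyper = syn.CohortHyper(sd_alpha_i=0, sd_beta_i=0, sd_det_alpha_i=0,
                                sd_det_beta_i=0, sd_alpha_d_i=0, sd_beta_d_i=0)
        cohort, truth = syn.make_cohort(cfg, hyper, seed=7)
        fat = syn.build_dataset(cfg, cohort, truth, seed=7).query(
            "session == 'fatigue'")
        fit = fit_probit_glmm(fat, model_id=1, compute_se=False, fix_re_sd=0.0)
        X = sm.add_constant(fat["lag_ms"].to_numpy(dtype=float))
        plain = sm.GLM(fat["choice_comparison"].to_numpy(), X,
                       family=sm.families.Binomial(
                           link=sm.families.links.Probit())).fit()
        lags = np.array([0.0, 50.0, 83.0])
        eta_glmm = fit.fixed_effects["alpha"] + fit.fixed_effects["beta"] * lags
        eta_plain = plain.params[0] + plain.params[1] * lags
        assert np.max(np.abs(eta_glmm - eta_plain)) < 1e-3


class TestInvariances:
    def test_participant_relabeling(self, exp1_small):
        _, _, _, trials = exp1_small
        fat = trials[trials["session"] == "fatigue"]
        relabeled = fat.copy()
        relabeled["participant_id"] = relabeled["participant_id"].map(
            {0: 13, 1: 2, 2: 27, 3: 1})
        f1 = fit_probit_glmm(fat, compute_se=False)
        f2 = fit_probit_glmm(relabeled, compute_se=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)
        assert f1.fixed_effects["beta"] == pytest.approx(
            f2.fixed_effects["beta"], rel=1e-4)
        assert sorted(f1.re_sd) == sorted(f2.re_sd)

    def test_lag_rescaling_covariance(self, exp1_small):
        """Lag in seconds instead of ms: slope x1000, logL unchanged."""
        _, _, _, trials = exp1_small
        fat = trials[trials["session"] == "fatigue"].copy()
        f_ms = fit_probit_glmm(fat, compute_se=False)
        fat["lag_ms"] = fat["lag_ms"] / 1000.0
        f_s = fit_probit_glmm(fat, compute_se=False)
        assert f_s.loglik == pytest.approx(f_ms.loglik, abs=1e-4)
        assert f_s.fixed_effects["beta"] == pytest.approx(
            1000.0 * f_ms.fixed_effects["beta"], rel=1e-3)

    def test_monotone_fitted_curves(self, exp1_full):
        _, _, _, trials = exp1_full
        fat = trials[trials["session"] == "fatigue"]
        fit = fit_probit_glmm(fat, compute_se=False)
        slopes = fit.subject_slopes("x")
        if (slopes > 0).all():
            lags = np.linspace(0, 83, 10)
            for _, row in fit.subject_effects.iterrows():
                eta = (fit.fixed_effects["alpha"] + row["const"]
                       + (fit.fixed_effects["beta"] + row["x"]) * lags)
                assert np.all(np.diff(eta) > 0)

    def test_single_predictor_level_rejected(self):
        rec = pd.DataFrame({"participant_id": [0] * 10 + [1] * 10,
                            "lag_ms": 50, "comparison_phase": 1,
                            "choice_comparison": [0, 1] * 10})
        with pytest.raises(ValueError, match="single predictor level"):
            fit_probit_glmm(rec)

    def test_model23_require_delay_probabilities(self, exp1_small):
        _, _, _, trials = exp1_small
        fat = trials[trials["session"] == "fatigue"]
        with pytest.raises(ValueError, match="delay"):
            fit_probit_glmm(fat, model_id=2)


class TestModelComparison:
    def test_identical_fits_tie(self, exp1_small):
        _, _, _, trials = exp1_small
        fat = trials[trials["session"] == "fatigue"]
        f = fit_probit_glmm(fat, compute_se=False)
        tab = model_comparison_aic([f, f])
        assert tab["delta_aic"].tolist() == [0.0, 0.0]

    def test_aic_formula(self, exp1_small):
        _, _, _, trials = exp1_small
        fat = trials[trials["session"] == "fatigue"]
        f = fit_probit_glmm(fat, compute_se=False)
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.k)
        assert f.k == 4

    def test_k_differs_by_two_at_equal_loglik(self):
        # synthetic fits: same logL, k 4 vs 6 -> delta AIC = 4
        from fatiguelag.glmm import GLMMFit
        base = dict(fixed_effects={"alpha": 0., "beta": 0.}, fixed_se={},
                    subject_effects=pd.DataFrame({"participant_id": [0]}),
                    loglik=-100.0, converged=True, n_obs=50, n_subjects=5)
        f1 = GLMMFit(model_id=1, re_sd={"a": 1., "b": 1.},
                     aic=-2 * -100 + 2 * 4, **base)
        f2 = GLMMFit(model_id=3, re_sd={"a": 1., "b": 1., "c": 1., "d": 1.},
                     aic=-2 * -100 + 2 * 6, **base)
        tab = model_comparison_aic([f1, f2])
        assert tab["delta_aic"].iloc[1] == pytest.approx(4.0)


class TestSlopeCorrelation:
    def test_identical_slopes_give_r_one(self, exp1_full):
        _, _, _, trials = exp1_full
        fat = trials[trials["session"] == "fatigue"]
        fit = fit_probit_glmm(fat, compute_se=False)
        if fit.subject_effects["x"].std() < 1e-12:
            pytest.skip("slope deviations fully shrunk on this dataset")
        r, _ = slope_correlation(fit, fit)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_recovers_induced_correlation(self):
        """Cohort with slope correlation 0.8: recovered r within +-0.15."""
        cfg = syn.experiment1_config(n_participants=50, blocks=15, seed=31)
        # slope spread well above the per-subject estimation noise, so the
        # posterior-mode slopes carry the correlation rather than shrinkage
        hyper = syn.CohortHyper(slope_corr=0.8, sd_beta_i=0.012,
                                sd_det_beta_i=0.02)
        cohort, truth = syn.make_cohort(cfg, hyper, seed=31)
        data = syn.build_dataset(cfg, cohort, truth, seed=31)
        fat = data[data["session"] == "fatigue"]
        dly = data[data["session"] == "delay"]
        f_fat = fit_probit_glmm(fat, compute_se=False)
        f_dly = fit_probit_glmm(dly, compute_se=False)
        r, _ = slope_correlation(f_fat, f_dly)
        assert r == pytest.approx(0.8, abs=0.15)

    def test_null_correlation_centred_on_zero(self):
        """Independent slopes: mean r over replicates near 0."""
        rs = []
        for seed in range(40, 52):
            cfg = syn.experiment1_config(n_participants=14, blocks=15, seed=seed)
            hyper = syn.CohortHyper(slope_corr=0.0, sd_beta_i=0.006,
                                    sd_det_beta_i=0.012)
            cohort, truth = syn.make_cohort(cfg, hyper, seed=seed)
            data = syn.build_dataset(cfg, cohort, truth, seed=seed)
            f_fat = fit_probit_glmm(data[data["session"] == "fatigue"],
                                    compute_se=False)
            f_dly = fit_probit_glmm(data[data["session"] == "delay"],
                                    compute_se=False)
            rs.append(slope_correlation(f_fat, f_dly)[0])
        assert abs(np.mean(rs)) < 0.2
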