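"""Generator contracts: determinism, schedules, kinematics, EMG, choices."""

import numpy as np
import pandas as pd
import pytest

from fatiguelag import signal_metrics as sm
from fatiguelag import synthetic as syn
from scipy.special import ndtr


class TestCohort:
    def test_zero_variance_degenerates_to_population_curve(self):
        cfg = syn.experiment1_config(n_participants=6, seed=1)
        hyper = syn.CohortHyper(sd_alpha_i=0, sd_beta_i=0, sd_det_alpha_i=0,
                                sd_det_beta_i=0, sd_alpha_d_i=0, sd_beta_d_i=0)
        cohort, _ = syn.make_cohort(cfg, hyper, seed=1)
        for p in cohort:
            assert p.alpha_i == p.beta_i == p.det_alpha_i == p.det_beta_i == 0.0

    def test_same_seed_identical_cohorts(self):
        cfg = syn.experiment1_config(n_participants=5, seed=9)
        c1, _ = syn.make_cohort(cfg, seed=9)
        c2, _ = syn.make_cohort(cfg, seed=9)
        assert c1 == c2

    def test_realized_sd_matches_hyper(self):
        """Sample SD of slope deviations within 10% of the configured 0.5."""
        cfg = syn.experiment1_config(n_participants=1000, seed=2)
        hyper = syn.CohortHyper(sd_beta_i=0.5)
        cohort, _ = syn.make_cohort(cfg, hyper, seed=2)
        betas = np.array([p.beta_i for p in cohort])
        assert np.std(betas, ddof=1) == pytest.approx(0.5, rel=0.10)

    def test_induced_slope_correlation(self):
        cfg = syn.experiment1_config(n_participants=2000, seed=3)
        hyper = syn.CohortHyper(slope_corr=0.8)
        cohort, _ = syn.make_cohort(cfg, hyper, seed=3)
        b = np.array([[p.beta_i, p.det_beta_i] for p in cohort])
        assert np.corrcoef(b.T)[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            syn.CohortHyper(sd_beta_i=-0.1)


class TestSchedules:
    def test_exp1_marginals(self, exp1_small):
        """Per block: five comparison cells x two sound conditions."""
        cfg, _, _, _ = exp1_small
        sched = syn.build_schedule(cfg, 0, "fatigue", seed=42)
        for _, blk in sched.groupby("block"):
            assert len(blk) == 10
            assert (blk["sound"] == 1).sum() == 5
            for lag in (50, 83):
                for phase in (1, 2):
                    assert ((blk["lag_ms"] == lag)
                            & (blk["comparison_phase"] == phase)).sum() == 2
            assert (blk["lag_ms"] == 0).sum() == 2

    def test_exp1_totals(self, exp1_full):
        """15 blocks -> 150 fatigue trials per participant, 75 sound-on."""
        _, _, _, trials = exp1_full
        fat = trials[trials["session"] == "fatigue"]
        per = fat.groupby("participant_id")
        assert (per.size() == 150).all()
        assert (per["sound"].sum() == 75).all()

    def test_exp2_each_lag_once_per_phase_per_block(self, exp2_small):
        cfg, _, _, trials = exp2_small
        fat = trials[(trials["session"] == "fatigue")
                     & (trials["participant_id"] == 0)]
        counts = fat.groupby(["lag_ms", "comparison_phase"]).size()
        assert set(counts.index.get_level_values(0)) == {-50, -33, 0, 33, 50}
        assert (counts == cfg.blocks_per_participant).all()

    def test_exp2_delay_session_17ms_steps(self, exp2_small):
        cfg, _, _, trials = exp2_small
        dly = trials[trials["session"] == "delay"]
        assert sorted(dly["lag_ms"].unique()) == [-50, -33, -17, 0, 17, 33, 50]
        one = dly[dly["participant_id"] == 0]
        assert len(one) == cfg.delay_session_blocks * 14

    def test_deterministic_trial_table(self, exp1_small):
        cfg, cohort, truth, trials = exp1_small
        again = syn.build_dataset(cfg, cohort, truth, seed=42)
        pd.testing.assert_frame_equal(trials, again)

    def test_asymmetric_exp2_lags_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            syn.experiment2_config().__class__(
                **{**syn.experiment2_config().__dict__,
                   "lag_conditions_ms": (-50, 0, 33, 50, 83)})


class TestKinematics:
    def test_single_cycle_interval_without_jitter(self):
        """Jitter CV 0: every cycle is exactly 1/2.14 s."""
        trace, cycles = syn.cyclic_trace(10.0, jitter_cv=0.0, seed=0)
        assert np.allclose(cycles["period_s"], 1 / 2.14)

    def test_mean_frequency_within_one_percent(self):
        """Jittered cycles still average the paced frequency over 100+ cycles."""
        trace, cycles = syn.cyclic_trace(60.0, jitter_cv=0.05, seed=1)
        assert len(cycles) > 100
        f = 1.0 / cycles["period_s"].mean()
        assert f == pytest.approx(2.14, rel=0.01)

    def test_block_structure_and_display_track(self, exp1_small):
        cfg, cohort, _, _ = exp1_small
        sched = syn.build_schedule(cfg, 0, "fatigue", seed=42)
        blk = sched[sched["block"] == 0].reset_index(drop=True)
        sim = syn.simulate_block(cohort[0], cfg, 0, blk, seed=42)
        assert sim.angle.fs == 500.0 and sim.display.fs == 60.0
        assert sim.angle.duration_s == pytest.approx(cfg.block_s)
        # display is a resampling of the capture track
        t60 = sim.display.t
        interp = np.interp(t60, sim.angle.t, sim.angle.data)
        assert np.max(np.abs(interp - sim.display.data)) < 1e-9

    def test_span_reduction_in_comparison_phase(self, exp1_small):
        cfg, cohort, _, _ = exp1_small
        sched = syn.build_schedule(cfg, 0, "fatigue", seed=42)
        blk = sched[sched["block"] == 0].reset_index(drop=True)
        sim = syn.simulate_block(cohort[0], cfg, 0, blk, seed=42)
        amp0 = cohort[0].amplitude_deg
        seg = sim.segments[(sim.segments["is_comparison"])
                           & (sim.segments["lag_ms"] == 83)].iloc[0]
        mids = sim.cycles["start_s"] + sim.cycles["period_s"] / 2
        in_seg = (mids >= seg["t0_s"]) & (mids < seg["t1_s"])
        assert np.allclose(sim.cycles.loc[in_seg, "amplitude_deg"], amp0 * (1 - 0.06))

    def test_wrong_schedule_length_rejected(self, exp1_small):
        cfg, cohort, _, _ = exp1_small
        sched = syn.build_schedule(cfg, 0, "fatigue", seed=42)
        blk = sched[sched["block"] == 0].reset_index(drop=True).iloc[:7]
        with pytest.raises(ValueError, match="inconsistent"):
            syn.simulate_block(cohort[0], cfg, 0, blk, seed=42)


class TestEMG:
    def test_no_drift_gives_flat_median_frequency(self):
        """Drift 0: block-wise MF trend slope CI contains zero over 20 blocks."""
        cfg = syn.experiment1_config(n_participants=1, blocks=20, seed=5)
        hyper = syn.CohortHyper(drift_hz_per_block=0.0)
        cohort, _ = syn.make_cohort(cfg, hyper, seed=5)
        mfs = []
        sched = syn.build_schedule(cfg, 0, "fatigue", seed=5)
        for b in range(20):
            blk = sched[sched["block"] == b].reset_index(drop=True)
            sim = syn.simulate_block(cohort[0], cfg, b, blk, seed=5)
            mfs.append(sm.median_frequency(sim.emg.data[0], 500.0))
        x = np.arange(20)
        import statsmodels.api as smod
        ols = smod.OLS(mfs, smod.add_constant(x)).fit()
        lo, hi = ols.conf_int()[1]
        assert lo <= 0.0 <= hi

    def test_configured_drift_recovered_at_block5(self):
        """-2 Hz/block from 110 Hz: block 5 measures 100 +- 3 Hz."""
        cfg = syn.experiment1_config(n_participants=1, blocks=6, seed=6)
        hyper = syn.CohortHyper(drift_hz_per_block=2.0, mf0_mean_hz=110.0,
                                mf0_sd_hz=0.0)
        cohort, _ = syn.make_cohort(cfg, hyper, seed=6)
        sched = syn.build_schedule(cfg, 0, "fatigue", seed=6)
        blk = sched[sched["block"] == 5].reset_index(drop=True)
        sim = syn.simulate_block(cohort[0], cfg, 5, blk, seed=6)
        for ch in range(2):
            assert sm.median_frequency(sim.emg.data[ch], 500.0) == pytest.approx(
                100.0, abs=3.0)

    def test_drift_trend_sign_detected(self):
        """With positive drift the fitted block trend is negative, p < 0.01."""
        cfg = syn.experiment1_config(n_participants=1, blocks=20, seed=7)
        hyper = syn.CohortHyper(drift_hz_per_block=1.0)
        cohort, _ = syn.make_cohort(cfg, hyper, seed=7)
        sched = syn.build_schedule(cfg, 0, "fatigue", seed=7)
        mfs = []
        for b in range(20):
            blk = sched[sched["block"] == b].reset_index(drop=True)
            sim = syn.simulate_block(cohort[0], cfg, b, blk, seed=7)
            mfs.append(sm.median_frequency(sim.emg.data[1], 500.0))
        import statsmodels.api as smod
        ols = smod.OLS(mfs, smod.add_constant(np.arange(20.0))).fit()
        assert ols.params[1] < 0 and ols.pvalues[1] < 0.01


class TestChoices:
    def test_chance_when_all_effects_zero(self):
        cfg = syn.experiment1_config(n_participants=1, blocks=15, seed=8)
        hyper = syn.CohortHyper(alpha=0.0, beta=0.0, sd_alpha_i=0, sd_beta_i=0,
                                sd_det_alpha_i=0, sd_det_beta_i=0,
                                sd_alpha_d_i=0, sd_beta_d_i=0)
        cohort, truth = syn.make_cohort(cfg, hyper, seed=8)
        table = pd.DataFrame({"lag_ms": [50] * 20000, "comparison_phase": 1,
                              "block": 0, "trial": 0, "sound": 0})
        rec = syn.simulate_choices(cohort[0], table, truth, "fatigue", seed=8)
        assert rec["p_true"].unique() == pytest.approx([0.5])
        assert rec["choice_comparison"].mean() == pytest.approx(0.5, abs=0.01)

    def test_saturation_at_large_slope(self):
        cfg = syn.experiment1_config(n_participants=1, seed=9)
        hyper = syn.CohortHyper(beta=1e6, sd_alpha_i=0, sd_beta_i=0)
        cohort, truth = syn.make_cohort(cfg, hyper, seed=9)
        table = pd.DataFrame({"lag_ms": [50] * 100, "comparison_phase": 2})
        rec = syn.simulate_choices(cohort[0], table, truth, "fatigue", seed=9)
        assert (rec["choice_comparison"] == 1).all()

    def test_binomial_rate_at_calibrated_slope(self):
        """beta chosen so Phi(beta*50) = 0.75: empirical rate 0.75 +- 0.01."""
        from scipy.special import ndtri
        beta = ndtri(0.75) / 50.0
        cfg = syn.experiment1_config(n_participants=1, seed=10)
        hyper = syn.CohortHyper(alpha=0.0, beta=beta, sd_alpha_i=0, sd_beta_i=0)
        cohort, truth = syn.make_cohort(cfg, hyper, seed=10)
        table = pd.DataFrame({"lag_ms": [50] * 10000, "comparison_phase": 1})
        rec = syn.simulate_choices(cohort[0], table, truth, "fatigue", seed=10)
        assert rec["choice_comparison"].mean() == pytest.approx(0.75, abs=0.01)

    def test_probabilities_reproducible_from_truth(self, exp1_small):
        """Stored p_true equals the probability recomputed from GroundTruth."""
        _, cohort, truth, trials = exp1_small
        fat = trials[trials["session"] == "fatigue"]
        for pid in fat["participant_id"].unique():
            sub = fat[fat["participant_id"] == pid]
            expect = [truth.p_fatigue(pid, x) for x in sub["lag_ms"]]
            assert sub["p_true"].to_numpy() == pytest.approx(expect)

    def test_model3_probability_composition(self):
        cfg = syn.experiment1_config(n_participants=3, seed=11)
        cohort, truth = syn.make_cohort(cfg, seed=11, model_id=3)
        h = truth.hyper
        p = cohort[1]
        x = 50.0
        eta = (h.alpha + p.alpha_i + p.alpha_d_i + (h.beta + p.beta_i) * x
               + (h.beta_d + p.beta_d_i) * truth.p_delay(1, x))
        assert truth.p_fatigue(1, x) == pytest.approx(float(ndtr(eta)))
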