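import numpy as np
import pandas as pd
import pytest

import sarcoxray as sx
from sarcoxray import mechanics as mech, synth


def hill_table(fmin=5.0, fmax=400.0, f50=45.0, nh=3.0,
               freqs=synth.EDL_FREQUENCIES_HZ, noise_sd=0.0, seed=0):
    spec = sx.MechSpec(hill=sx.HillSpec(fmin, fmax, f50, nh),
                       noise_sd={"force_frequency": noise_sd}, seed=seed)
    return sx.simulate_force_frequency(spec, freqs)


class TestForceFrequencyFit:
    def test_noiseless_recovery_to_four_significant_figures(self):
        fit = mech.fit_force_frequency(hill_table())
        assert fit.fmin == pytest.approx(5.0, rel=1e-4)
        assert fit.fmax == pytest.approx(400.0, rel=1e-4)
        assert fit.f50_hz == pytest.approx(45.0, rel=1e-4)
        assert fit.nh == pytest.approx(3.0, rel=1e-4)
        assert fit.f50_in_range

    def test_model_midpoint_at_f50(self):
        fit = mech.fit_force_frequency(hill_table())
        assert fit.predict(fit.f50_hz) == pytest.approx((fit.fmin + fit.fmax) / 2, rel=1e-9)
        assert fit.predict_normalized(1e6) == pytest.approx(1.0, rel=1e-6)

    def test_force_scale_equivariance(self):
        tab = hill_table(noise_sd=5.0, seed=3)
        fit1 = mech.fit_force_frequency(tab)
        tab2 = tab.assign(force_mn=tab.force_mn * 2.5)
        fit2 = mech.fit_force_frequency(tab2)
        assert fit2.fmax == pytest.approx(2.5 * fit1.fmax, rel=1e-6)
        assert fit2.fmin == pytest.approx(2.5 * fit1.fmin, rel=1e-4, abs=1e-3)
        assert fit2.f50_hz == pytest.approx(fit1.f50_hz, rel=1e-6)
        assert fit2.nh == pytest.approx(fit1.nh, rel=1e-6)

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(mech.FitError):
            mech.fit_force_frequency(hill_table(freqs=(10.0, 40.0, 80.0, 150.0)))

    def test_f50_bias_small_under_noise(self):
        f50s = [mech.fit_force_frequency(hill_table(noise_sd=5.0, seed=s)).f50_hz
                for s in range(200)]
        assert abs(np.mean(f50s) - 45.0) < 1.0


class TestForcePCaFit:
    def test_noiseless_recovery(self):
        spec = sx.MechSpec(pca=sx.PCaSpec(fmax=120.0, pca50=5.9, nh=5.0))
        fit = mech.fit_force_pca(sx.simulate_force_pca(spec))
        assert fit.fmax == pytest.approx(120.0, rel=1e-6)
        assert fit.pca50 == pytest.approx(5.9, abs=1e-6)
        assert fit.nh == pytest.approx(5.0, rel=1e-6)

    def test_half_maximal_force_at_pca50(self):
        spec = sx.MechSpec()
        fit = mech.fit_force_pca(sx.simulate_force_pca(spec))
        assert fit.predict(fit.pca50) == pytest.approx(fit.fmax / 2, rel=1e-9)

    def test_pca_offset_equivariance(self):
        spec = sx.MechSpec(pca=sx.PCaSpec(fmax=120.0, pca50=5.9, nh=5.0),
                           noise_sd={"force_pca": 2.0}, seed=5)
        tab = sx.simulate_force_pca(spec)
        fit1 = mech.fit_force_pca(tab)
        fit2 = mech.fit_force_pca(tab.assign(pca=tab.pca + 0.3))
        assert fit2.pca50 == pytest.approx(fit1.pca50 + 0.3, abs=1e-6)
        assert fit2.nh == pytest.approx(fit1.nh, rel=1e-6)


class TestKtrFit:
    def test_noiseless_recovery(self):
        spec = sx.MechSpec(ktr=sx.KtrSpec(fss=60.0, ktr_per_s=20.0, k_per_s=2.0, c=1.5))
        fit = mech.fit_ktr(sx.simulate_ktr_trace(spec))
        assert fit.fss == pytest.approx(60.0, rel=1e-6)
        assert fit.ktr_per_s == pytest.approx(20.0, rel=1e-6)
        assert fit.k_per_s == pytest.approx(2.0, rel=1e-6)
        assert fit.c == pytest.approx(1.5, abs=1e-6)

    def test_rates_returned_sorted_descending(self):
        spec = sx.MechSpec(ktr=sx.KtrSpec(fss=60.0, ktr_per_s=20.0, k_per_s=2.0))
        fit = mech.fit_ktr(sx.simulate_ktr_trace(spec))
        assert fit.ktr_per_s > fit.k_per_s

    def test_trace_anchored_at_offset(self):
        spec = sx.MechSpec(ktr=sx.KtrSpec(c=3.0))
        fit = mech.fit_ktr(sx.simulate_ktr_trace(spec))
        assert fit.predict(0.0) == pytest.approx(fit.c, rel=1e-9)

    def test_free_amplitude_variant_reports_share(self):
        # 90/10 amplitude split: fast-phase share recovered
        t = np.arange(0.0, 2.0, 1e-3)
        y = 90.0 * (1 - np.exp(-20.0 * t)) + 10.0 * (1 - np.exp(-2.0 * t))
        fit = mech.fit_ktr(pd.DataFrame({"t_s": t, "force": y}), shared_amplitude=False)
        assert fit.fast_phase_share == pytest.approx(0.9, abs=1e-3)
        assert fit.ktr_per_s == pytest.approx(20.0, rel=1e-3)

    def test_ktr_scale_equivariance(self):
        spec = sx.MechSpec(ktr=sx.KtrSpec(fss=60.0, ktr_per_s=20.0, k_per_s=2.0),
                           noise_sd={"ktr": 1.0}, seed=2)
        tab = sx.simulate_ktr_trace(spec)
        fit1 = mech.fit_ktr(tab)
        fit2 = mech.fit_ktr(tab.assign(force=3.0 * tab.force))
        assert fit2.ktr_per_s == pytest.approx(fit1.ktr_per_s, rel=1e-6)
        assert fit2.fss == pytest.approx(3.0 * fit1.fss, rel=1e-6)


class TestUnloadedVelocity:
    def test_noiseless_round_trip_exact(self):
        spec = sx.MechSpec(velocity=sx.VelocitySpec(v_lengths_per_s=2.0, t0_ms=2.0))
        fit = mech.unloaded_velocity(sx.simulate_slack_test(spec))
        assert fit.velocity_lengths_per_s == pytest.approx(2.0, rel=1e-9)
        assert fit.intercept_s == pytest.approx(0.002, abs=1e-12)

    def test_perfect_line_gives_exact_slope(self):
        dist_pct = np.array([8.0, 9.0, 10.0, 11.0, 13.0, 15.0])
        delay = 0.001 + (dist_pct / 100.0) / 3.5
        fit = mech.unloaded_velocity(pd.DataFrame({"slack_pct": dist_pct, "delay_s": delay}))
        assert fit.velocity_lengths_per_s == pytest.approx(3.5, rel=1e-9)

    def test_velocity_recovered_within_2_se_under_noise(self):
        spec = sx.MechSpec(velocity=sx.VelocitySpec(v_lengths_per_s=2.0, t0_ms=2.0),
                           noise_sd={"slack": 0.002}, seed=4)
        fit = mech.unloaded_velocity(sx.simulate_slack_test(spec))
        assert abs(fit.velocity_lengths_per_s - 2.0) < 2 * fit.velocity_se


class TestGeometryNormalization:
    def test_pcsa_worked_example(self):
        g = mech.MuscleGeometry(mass_mg=11.0, l0_mm=13.0, muscle_type="EDL")
        assert g.fiber_length_mm == pytest.approx(6.63)
        assert mech.pcsa(g) == pytest.approx(1.571, abs=1e-3)

    def test_soleus_ratio_applied(self):
        g = mech.MuscleGeometry(mass_mg=10.0, l0_mm=10.0, muscle_type="soleus")
        assert g.fiber_ratio == 0.72
        assert mech.pcsa(g) == pytest.approx(10.0 / (1.056 * 7.2))

    def test_specific_force(self):
        assert mech.specific_force(0.0, 1.5) == 0.0
        assert mech.specific_force(300.0, 1.5) == pytest.approx(200.0)
        with pytest.raises(ValueError):
            mech.specific_force(100.0, 0.0)

    def test_unknown_muscle_type_rejected(self):
        with pytest.raises(ValueError):
            mech.MuscleGeometry(mass_mg=10.0, l0_mm=10.0, muscle_type="diaphragm")


class TestTetanusKinetics:
    def test_analytic_half_times_of_exponential_trace(self):
        tab = sx.simulate_tetanus(fmax=400.0, rise_rate_per_s=40.0,
                                  decay_rate_per_s=25.0, stim_end_s=0.5)
        res = mech.tetanus_kinetics(tab, stim_onset_s=0.0, stim_end_s=0.5)
        assert res["time_to_half_force_ms"] == pytest.approx(1e3 * np.log(2) / 40.0, abs=0.5)
        assert res["time_to_half_relaxation_ms"] == pytest.approx(1e3 * np.log(2) / 25.0, abs=0.5)

    def test_constant_trace_has_no_crossing(self):
        t = np.arange(0.0, 1.0, 1e-3)
        tab = pd.DataFrame({"t_s": t, "force_mn": np.full_like(t, 100.0)})
        with pytest.raises(mech.FitError):
            mech.tetanus_kinetics(tab, stim_end_s=0.5)

    def test_interpolation_robust_to_sampling_rate(self):
        fine = sx.simulate_tetanus(dt_s=5e-4)
        coarse = sx.simulate_tetanus(dt_s=1e-3)
        r1 = mech.tetanus_kinetics(fine, stim_end_s=0.5)
        r2 = mech.tetanus_kinetics(coarse, stim_end_s=0.5)
        assert abs(r1["time_to_half_force_ms"] - r2["time_to_half_force_ms"]) < 1.0


class TestActiveStiffness:
    DL = np.array([-0.9, -0.6, -0.3, 0.3, 0.6, 0.9])

    def test_exact_line_recovered(self):
        df = pd.DataFrame({"dl_pct": self.DL, "df": 12.0 * self.DL + 1.0})
        fit = mech.active_stiffness(df)
        assert fit.slope == pytest.approx(12.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)

    def test_sign_flip_invariance(self):
        df = pd.DataFrame({"dl_pct": self.DL, "df": 12.0 * self.DL})
        flipped = pd.DataFrame({"dl_pct": -self.DL, "df": -12.0 * self.DL})
        assert mech.active_stiffness(flipped).slope == pytest.approx(
            mech.active_stiffness(df).slope, rel=1e-12)

    def test_se_matches_closed_form_ols(self, rng):
        y = 12.0 * self.DL + rng.normal(0, 0.5, self.DL.size)
        fit = mech.active_stiffness(pd.DataFrame({"dl_pct": self.DL, "df": y}))
        resid = y - (fit.intercept + fit.slope * self.DL)
        s2 = resid @ resid / (len(self.DL) - 2)
        sxx = np.sum((self.DL - self.DL.mean()) ** 2)
        assert fit.slope_se == pytest.approx(np.sqrt(s2 / sxx), rel=1e-9)


class TestCompareCurvesFtest:
    def test_identical_datasets_give_f_zero_p_one(self):
        tab = hill_table(noise_sd=5.0, seed=7)
        res = mech.compare_curves_ftest([tab, tab], model="hill_ff")
        assert res["F"] == pytest.approx(0.0, abs=1e-6)
        assert res["p"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_sum_of_squares(self):
        # oracle: recompute pooled and separate SS directly from refits
        tabs = [hill_table(noise_sd=8.0, seed=s) for s in (1, 2)]
        res = mech.compare_curves_ftest(tabs, model="hill_ff")
        ss_sep = sum(mech.fit_force_frequency(t).rss for t in tabs)
        pooled = pd.concat(tabs, ignore_index=True)
        ss_pool = mech.fit_force_frequency(pooled).rss
        n = sum(len(t) for t in tabs)
        dfd = n - 4 * 2
        dfn = (n - 4) - dfd
        f_oracle = ((ss_pool - ss_sep) / dfn) / (ss_sep / dfd)
        assert res["F"] == pytest.approx(f_oracle, rel=1e-9)
        assert res["dfn"] == dfn and res["dfd"] == dfd

    def test_shifted_f50_detected(self):
        # curves differing in F50 by 3 noise sd: decisively rejected
        hits = 0
        for s in range(20):
            a = hill_table(f50=45.0, noise_sd=2.0, seed=s)
            b = hill_table(f50=60.0, noise_sd=2.0, seed=1000 + s)
            res = mech.compare_curves_ftest([a, b], model="hill_ff")
            hits += res["p"] < 0.001
        assert hits >= 19

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            mech.compare_curves_ftest([hill_table()], model="hill_ff")
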