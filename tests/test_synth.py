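"""Synthetic-experiment generator: infusion profiles, disposal model,
sensor dynamics, noise model and study layout."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cgmdyn import synth, types
from cgmdyn.synth import DisposalParams, StudyConfig
from cgmdyn.types import InfusionEvent, NoiseConfig, TrueDynamics


class TestInfusionProfile:
    def test_standard_meal_rate_and_integral(self):
        prof = synth.make_infusion_profile(
            [InfusionEvent("meal", 600.0, 1800.0, 245.0)], 1.0, 3600.0)
        inside = (prof.times >= 600) & (prof.times < 2400)
        assert np.allclose(prof.values[inside], 245.0 / 1800.0)
        assert np.all(prof.values[prof.times < 600] == 0)
        assert np.all(prof.values[prof.times >= 2400] == 0)
        assert abs(np.trapezoid(prof.values, dx=1.0) - 245.0) < 1e-9 * 245

    def test_empty_events_all_zero(self):
        prof = synth.make_infusion_profile([], 1.0, 600.0)
        assert np.all(prof.values == 0)

    def test_two_meals_integral_adds(self):
        evs = [InfusionEvent("meal", 0.0, 1800.0, 245.0),
               InfusionEvent("meal", 3600.0, 1800.0, 245.0)]
        prof = synth.make_infusion_profile(evs, 1.0, 7200.0)
        assert abs(prof.values.sum() - 490.0) < 1e-9 * 490

    def test_overlapping_events_rejected(self):
        evs = [InfusionEvent("meal", 0.0, 1800.0, 245.0),
               InfusionEvent("meal", 900.0, 1800.0, 245.0)]
        with pytest.raises(ValueError, match="overlap"):
            synth.make_infusion_profile(evs, 1.0)

    def test_misaligned_window_keeps_exact_dose(self):
        # event edges falling inside grid cells use overlap fractions
        prof = synth.make_infusion_profile(
            [InfusionEvent("meal", 100.5, 1799.2, 245.0)], 1.0, 3600.0)
        assert abs(np.sum(prof.values) - 245.0) < 1e-9 * 245


class TestArterialDisposal:
    def test_zero_infusion_stays_at_basal(self):
        prof = synth.make_infusion_profile([], 1.0, 1200.0)
        dense, _ = synth.simulate_arterial(prof, seed=0)
        assert np.allclose(dense.values, 5.0)

    def test_default_meal_rise_in_printed_band(self, meal_arterial):
        dense, _ = meal_arterial
        rise = dense.values.max() - DisposalParams().G_basal
        assert 3.5 <= rise <= 5.5

    def test_doubled_dose_without_clearance_doubles_rise(self):
        # closed form: rise = integral(u) / (V_d * 0.18016) when k_cl = 0
        disp = DisposalParams(k_cl=0.0)
        evs1 = [InfusionEvent("meal", 60.0, 600.0, 100.0)]
        evs2 = [InfusionEvent("meal", 60.0, 600.0, 200.0)]
        p1 = synth.make_infusion_profile(evs1, 1.0, 1200.0)
        p2 = synth.make_infusion_profile(evs2, 1.0, 1200.0)
        d1, _ = synth.simulate_arterial(p1, disp, seed=0)
        d2, _ = synth.simulate_arterial(p2, disp, seed=0)
        r1 = d1.values[-1] - 5.0
        r2 = d2.values[-1] - 5.0
        expected = 100.0 / (150.0 * synth.GLUCOSE_MOLAR_MASS / 1000.0)
        assert abs(r1 - expected) < 1e-9
        assert abs(r2 - 2 * r1) < 1e-9

    def test_negative_glucose_rejected(self):
        prof = synth.make_infusion_profile([], 1.0, 600.0)
        with pytest.raises(ValueError):
            DisposalParams(G_basal=0.5)

    def test_baseline_slots_present_around_each_event(self, meal_arterial,
                                                      meal_events):
        _, sparse = meal_arterial
        t0 = meal_events[0].t_start
        for slot in (t0, t0 - 300, t0 - 600, t0 - 900):
            assert np.min(np.abs(sparse.times - slot)) <= 1.0


class TestSensorModel:
    def test_unit_gain_constant_input_steady_state(self):
        c = 4.2
        arterial = types.Series(np.arange(3000.0), np.full(3000, c))
        dyn = TrueDynamics(K=1.0, tau=300.0, theta=60.0, site="SC_left")
        _, truth = synth.simulate_sensor(
            arterial, dyn, NoiseConfig(p_outlier=0, p_dropout=0), seed=0)
        assert abs(truth.values[-1] - c) < 1e-9

    def test_gain_scales_steady_state(self):
        arterial = types.Series(np.arange(4000.0), np.full(4000, 3.0))
        dyn = TrueDynamics(K=2.0, tau=200.0, theta=0.0, site="SC_left")
        _, truth = synth.simulate_sensor(
            arterial, dyn, NoiseConfig(p_outlier=0, p_dropout=0), seed=0)
        assert abs(truth.values[-1] - 6.0) < 1e-9

    def test_step_response_matches_closed_form(self):
        n, theta, tau, K = 4000, 120, 450.0, 1.3
        u = np.concatenate([np.zeros(500), np.ones(n - 500)])
        y = synth.first_order_response(u, K, tau, theta)
        t = np.arange(n)
        rel = t - 500 - theta
        expected = np.where(rel >= 0, K * (1 - np.exp(-rel / tau)), 0.0)
        assert np.max(np.abs(y - expected)) <= 1e-6 * max(K, 1.0)

    def test_exact_discretization_matches_ode_oracle(self):
        # adaptive ODE solve of the compartment model on a random smooth
        # input, integrating each 1 s cell with its held input value
        rng = np.random.default_rng(4)
        n = 600
        knots = rng.uniform(3, 9, 10)
        u = np.interp(np.arange(n), np.linspace(0, n - 1, 10), knots)
        tau, K = 240.0, 0.9
        arterial = types.Series(np.arange(float(n)), u)
        dyn = TrueDynamics(K=K, tau=tau, theta=0.0, site="SC_left")
        _, truth = synth.simulate_sensor(
            arterial, dyn, NoiseConfig(p_outlier=0, p_dropout=0), seed=0)

        y = np.empty(n)
        y[0] = K * u[0]
        for k in range(n - 1):
            sol = solve_ivp(lambda t, yy: (K * u[k] - yy) / tau,
                            (0.0, 1.0), [y[k]], rtol=1e-11, atol=1e-13)
            y[k + 1] = sol.y[0, -1]
        assert np.max(np.abs(y - truth.values)) < 1e-6

    def test_sampling_cadence_and_minute_hold(self, noisy_sensor):
        raw, truth = noisy_sensor
        gaps = np.diff(raw.times)
        # dropouts create multiples of the base cadence
        assert gaps.min() >= 20.0 - 1e-9
        base = gaps[gaps <= 22.0]
        assert len(base) > 0.9 * len(gaps)
        assert base.max() <= 22.0 + 1e-9

    def test_noise_sd_matches_config_within_2pct(self):
        for g_const, want in [(4.0, 0.83 / 2), (10.0, 0.075 * 10.0)]:
            arterial = types.Series(np.arange(3000.0), np.full(3000, g_const))
            dyn = TrueDynamics(K=1.0, tau=60.0, theta=0.0, site="SC_left")
            devs = []
            for s in range(800):  # ~1e5 total samples
                raw, truth = synth.simulate_sensor(
                    arterial, dyn, NoiseConfig(p_outlier=0, p_dropout=0), seed=s)
                i = np.floor(raw.times).astype(int)
                held = truth.values[(i // 60) * 60]
                devs.append(raw.values - held)
            sd = np.std(np.concatenate(devs))
            assert abs(sd - want) / want < 0.02

    def test_theta_beyond_leadin_rejected(self):
        arterial = types.Series(np.arange(100.0), np.full(100, 5.0))
        dyn = TrueDynamics(K=1.0, tau=60.0, theta=500.0, site="SC_left")
        with pytest.raises(ValueError, match="lead-in"):
            synth.simulate_sensor(arterial, dyn, NoiseConfig(), seed=0)


class TestFluidSamples:
    def test_no_drift_zero_noise_equals_truth(self):
        truth = types.Series(np.arange(3601.0), np.linspace(5, 9, 3601))
        s = synth.simulate_fluid_samples(truth, 300.0, noise_sd=0.0, seed=0)
        idx = np.round(s.times).astype(int)
        assert np.allclose(s.values, truth.values[idx])

    def test_sample_count_includes_both_ends(self):
        truth = types.Series(np.arange(3601.0), np.full(3601, 5.0))
        s = synth.simulate_fluid_samples(truth, 300.0, noise_sd=0.0, seed=0)
        assert len(s) == 13
        assert s.times[0] == 0.0 and s.times[-1] == 3600.0

    def test_storage_drift_mean_offset(self):
        truth = types.Series(np.arange(600001.0), np.full(600001, 5.0))
        s = synth.simulate_fluid_samples(truth, 60.0, noise_sd=0.0,
                                         storage_drift=0.1, seed=1)
        assert len(s) >= 10000
        assert abs(np.mean(s.values - 5.0) - 0.1) < 0.005

    def test_interval_below_minute_rejected(self):
        truth = types.Series(np.arange(600.0), np.full(600, 5.0))
        with pytest.raises(ValueError):
            synth.simulate_fluid_samples(truth, 30.0)


class TestStudyLayout:
    def test_same_seed_reproduces_exactly(self):
        cfg = StudyConfig(n_pigs=1, events=[InfusionEvent("meal", 1200.0, 1800.0, 245.0)],
                          t_end=4800.0)
        a = synth.simulate_study(cfg, seed=9)
        b = synth.simulate_study(cfg, seed=9)
        for ea, eb in zip(a.experiments, b.experiments):
            assert np.array_equal(ea.arterial_samples.values, eb.arterial_samples.values)
            for sa, sb in zip(ea.sensors, eb.sensors):
                assert sa.dyn == sb.dyn
                assert np.array_equal(sa.raw.times, sb.raw.times)
                assert np.array_equal(sa.raw.values, sb.raw.values)

    def test_six_sensors_four_ip_two_sc(self, tiny_study):
        for exp in tiny_study.experiments:
            sites = [r.dyn.site for r in exp.sensors]
            assert len(sites) == 6
            assert sum(s.startswith("IP_") for s in sites) == 4
            assert sum(s.startswith("SC_") for s in sites) == 2
            # fluid sampled at every IP site
            assert set(exp.fluid_samples) == set(types.IP_SITES)

    def test_challenge_recording_count(self, tiny_study):
        n_challenges = len(tiny_study.config.events)
        n_recordings = sum(len(e.sensors) for e in tiny_study.experiments)
        assert n_recordings * n_challenges == 2 * 6 * 2

    def test_sensor_truth_satisfies_compartment_model(self, tiny_study):
        # dense truth must solve the model against arterial truth
        exp = tiny_study.experiments[0]
        rec = exp.sensors[0]
        redo = synth.first_order_response(
            exp.arterial_truth.values, rec.dyn.K, rec.dyn.tau,
            int(round(rec.dyn.theta)))
        assert np.max(np.abs(redo - rec.truth.values)) < 1e-9


class TestEventValidation:
    @given(st.floats(min_value=-1e3, max_value=0.0))
    @settings(max_examples=20, deadline=None)
    def test_nonpositive_meal_duration_rejected(self, dur):
        with pytest.raises(ValueError):
            InfusionEvent("meal", 0.0, dur, 245.0)

    def test_clamp_duration_band(self):
        InfusionEvent("clamp", 0.0, 5400.0, 5.0)
        with pytest.raises(ValueError):
            InfusionEvent("clamp", 0.0, 3600.0, 5.0)

    def test_orientation_site_consistency(self):
        with pytest.raises(ValueError):
            TrueDynamics(K=1, tau=100, theta=0, site="SC_left",
                         orientation="toward_wall")
        with pytest.raises(ValueError):
            TrueDynamics(K=1, tau=100, theta=0, site="IP_cranial_left",
                         orientation="n/a")
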