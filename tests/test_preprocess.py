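"""Median filter, Kalman smoother and monotone interpolation."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmdyn import preprocess, synth, types
from cgmdyn.preprocess import (
    SmootherParams,
    interpolate_arterial,
    iso15197_variance,
    kalman_smooth,
    median_filter,
)
from cgmdyn.types import NoiseConfig, SensorSeries, Series, TrueDynamics


def _stream(values, dt=21.0):
    values = np.asarray(values, dtype=float)
    return SensorSeries(np.arange(len(values)) * dt, values)


class TestMedianFilter:
    def test_constant_stream_unchanged(self):
        out = median_filter(_stream([5, 5, 5, 5, 5]))
        assert np.array_equal(out.values, np.full(5, 5.0))

    def test_single_spike_removed(self):
        out = median_filter(_stream([5, 5, 12, 5, 5]), 5)
        assert np.array_equal(out.values, np.full(5, 5.0))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(_stream([1, 2, 3]), 4)

    def test_timestamps_unchanged(self):
        s = _stream(np.arange(10.0))
        out = median_filter(s, 5)
        assert np.array_equal(out.times, s.times)

    @given(st.lists(st.floats(min_value=1, max_value=20), min_size=3,
                    max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_sorting_oracle_with_shrunken_edges(self, vals):
        out = median_filter(_stream(vals), 5)
        v = np.asarray(vals)
        for i in range(len(v)):
            lo, hi = max(0, i - 2), min(len(v), i + 3)
            assert out.values[i] == sorted(v[lo:hi])[(hi - lo) // 2] or \
                out.values[i] == np.median(v[lo:hi])


class TestMeasurementVariance:
    def test_branch_values(self):
        assert iso15197_variance(5.0) == pytest.approx((0.83 / 2) ** 2)
        assert iso15197_variance(5.0) == pytest.approx(0.172225)
        assert iso15197_variance(10.0) == pytest.approx(0.5625)
        # boundary belongs to the low branch
        assert iso15197_variance(5.55) == pytest.approx((0.83 / 2) ** 2)


class TestKalmanSmoother:
    def test_constant_noiseless_stream_recovered(self):
        n = 40  # ~ 880 s of reads at 22 s
        s = _stream(np.full(n, 5.0), dt=22.0)
        sm = kalman_smooth(s)
        after = sm.times >= sm.times[0] + 120.0
        assert np.nanmax(np.abs(sm.mean[after] - 5.0)) < 1e-3
        assert np.nanmax(np.abs(sm.rate[after])) < 1e-3

    def test_uniform_grid_with_sd_and_rate(self, smoothed_sensor):
        sm = smoothed_sensor
        assert np.allclose(np.diff(sm.times), 1.0)
        assert np.all(sm.sd >= 0)
        assert sm.mean.shape == sm.rate.shape == sm.times.shape

    def test_smoothing_reduces_rmse_vs_raw(self, noisy_sensor, smoothed_sensor):
        raw, truth = noisy_sensor
        sm = smoothed_sensor
        i_raw = np.floor(raw.times - truth.times[0]).astype(int)
        rmse_raw = np.sqrt(np.mean((raw.values - truth.values[i_raw]) ** 2))
        idx = np.round(sm.times - truth.times[0]).astype(int)
        rmse_sm = np.sqrt(np.nanmean((sm.mean - truth.values[idx]) ** 2))
        assert rmse_sm < rmse_raw

    def test_posterior_band_covers_truth(self, meal_arterial):
        # calibration of the +/-2 SD band, pooled over replicates
        # (smoothing errors are autocorrelated, so per-replicate coverage
        # fluctuates; calibration is a population property)
        dense, _ = meal_arterial
        dyn = TrueDynamics(K=1.0, tau=732.0, theta=170.0,
                           site="IP_cranial_left", orientation="toward_wall")
        inside = total = 0
        for seed in range(4):
            raw, truth = synth.simulate_sensor(dense, dyn, NoiseConfig(),
                                               seed=seed)
            sm = kalman_smooth(median_filter(raw, 5))
            idx = np.round(sm.times - truth.times[0]).astype(int)
            ok = np.isfinite(sm.mean)
            inside += np.sum(
                np.abs(sm.mean[ok] - truth.values[idx][ok]) <= 2 * sm.sd[ok])
            total += ok.sum()
        assert inside / total >= 0.90

    def test_outlier_pass_flags_spikes_but_keeps_clean_points(self):
        # un-filtered stream with gross spikes: the smoother's own outlier
        # pass must catch them without eating clean measurements
        rng = np.random.default_rng(8)
        n = 120
        t = np.arange(n) * 21.0
        base = 5.0 + 0.415 * rng.standard_normal(n)
        spike_at = np.array([20, 21, 60, 61, 90])
        base[spike_at] += 4.0
        sm = kalman_smooth(SensorSeries(t, base))
        assert sm.removed_count >= 4  # >= 80% of the 5 spikes
        assert sm.removed_count <= 5 + int(0.02 * (n - 5))

    def test_pipeline_outlier_sensitivity_and_specificity(self, meal_arterial):
        # combined median filter + smoother on ISO noise with default
        # outlier rate: every isolated outlier corrected or removed,
        # < 2% of clean samples removed
        dense, _ = meal_arterial
        dyn = TrueDynamics(K=1.0, tau=600.0, theta=120.0,
                           site="IP_caudal_right", orientation="toward_wall")
        raw, _ = synth.simulate_sensor(dense, dyn, NoiseConfig(p_dropout=0.0),
                                       seed=33)
        filt = median_filter(raw, 5)
        sm = kalman_smooth(filt)
        out_mask = raw.flags == "outlier"
        corrected = np.abs(filt.values - raw.values) > 0.5
        assert out_mask.sum() > 0
        sens = np.mean(corrected[out_mask])
        assert sens >= 0.8
        assert sm.removed_count <= 0.02 * (~out_mask).sum()

    def test_all_outliers_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            kalman_smooth(_stream([5.0] * 5))

    def test_dropout_gap_leaves_nan(self):
        rng = np.random.default_rng(3)
        t = np.arange(60) * 21.0
        v = 5.0 + 0.1 * rng.standard_normal(60)
        keep = (t < 400) | (t > 700)  # 300 s hole
        sm = kalman_smooth(SensorSeries(t[keep], v[keep]))
        # measurement support sits on minute-update instants (360 and 660
        # bracket the hole); beyond the 90 s horizon the grid is NaN
        mid = (sm.times > 470) & (sm.times < 550)
        assert np.all(np.isnan(sm.mean[mid]))
        assert np.all(np.isfinite(sm.mean[sm.times <= 400]))


class TestMonotoneInterpolation:
    def test_passes_through_samples(self):
        s = Series([0.0, 100.0, 250.0, 400.0], [5.0, 6.0, 8.5, 7.0])
        dense = interpolate_arterial(s)
        for t, v in zip(s.times, s.values):
            assert dense.values[int(t)] == pytest.approx(v, abs=1e-12)

    def test_monotone_input_gives_monotone_output(self):
        s = Series([0.0, 60.0, 200.0, 380.0, 500.0], [4.0, 4.5, 6.0, 8.0, 8.2])
        dense = interpolate_arterial(s)
        assert np.all(np.diff(dense.values) >= -1e-12)

    def test_no_overshoot_beyond_sample_extrema(self):
        s = Series([0.0, 50.0, 100.0, 150.0, 200.0],
                   [5.0, 9.0, 5.5, 9.5, 5.0])
        dense = interpolate_arterial(s)
        assert dense.values.max() <= 9.5 + 1e-12
        assert dense.values.min() >= 5.0 - 1e-12

    def test_matches_independent_monotone_hermite_oracle(self):
        # independent implementation of the weighted-harmonic-mean
        # monotone Hermite slopes
        x = np.array([0.0, 40.0, 90.0, 160.0, 250.0, 360.0])
        y = np.array([5.0, 5.3, 6.8, 7.0, 6.1, 5.9])

        h = np.diff(x)
        delta = np.diff(y) / h
        d = np.zeros(len(x))
        for i in range(1, len(x) - 1):
            if delta[i - 1] * delta[i] <= 0:
                d[i] = 0.0
            else:
                w1 = 2 * h[i] + h[i - 1]
                w2 = h[i] + 2 * h[i - 1]
                d[i] = (w1 + w2) / (w1 / delta[i - 1] + w2 / delta[i])
        # one-sided endpoint slopes (shape-preserving form)
        def endpoint(h0, h1, d0, d1):
            s = ((2 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
            if np.sign(s) != np.sign(d0):
                return 0.0
            if np.sign(d0) != np.sign(d1) and abs(s) > 3 * abs(d0):
                return 3 * d0
            return s
        d[0] = endpoint(h[0], h[1], delta[0], delta[1])
        d[-1] = endpoint(h[-1], h[-2], delta[-1], delta[-2])

        def hermite(t):
            i = np.searchsorted(x, t) - 1
            i = np.clip(i, 0, len(x) - 2)
            s = (t - x[i]) / h[i]
            h00 = 2 * s**3 - 3 * s**2 + 1
            h10 = s**3 - 2 * s**2 + s
            h01 = -2 * s**3 + 3 * s**2
            h11 = s**3 - s**2
            return (h00 * y[i] + h10 * h[i] * d[i]
                    + h01 * y[i + 1] + h11 * h[i] * d[i + 1])

        mid = (x[:-1] + x[1:]) / 2
        dense = interpolate_arterial(Series(x, y))
        from scipy.interpolate import PchipInterpolator
        got = PchipInterpolator(x, y)(mid)
        want = hermite(mid)
        assert np.max(np.abs(got - want)) < 1e-9
        # and the dense grid values agree at integer midpoints
        for t in mid:
            assert dense.values[int(t) - int(dense.times[0])] == pytest.approx(
                hermite(float(int(t))), abs=1e-9)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            interpolate_arterial(Series([0.0, 0.0, 10.0], [1.0, 2.0, 3.0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            interpolate_arterial(Series([0.0], [5.0]))
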