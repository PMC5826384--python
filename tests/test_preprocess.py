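"""Tests for time-series cleaning and motion QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conneff.preprocess import (
    MotionParams,
    RoiTimeSeries,
    SignalCleaner,
    bandpass_filter,
    clean_timeseries,
    detrend_linear,
    framewise_displacement,
    friston24,
    motion_exclusion,
    regress_nuisance,
)
from ._oracles import ols_residuals


def make_ts(data, tr=2.0):
    return RoiTimeSeries(subject_id="s", data=np.asarray(data, float),
                         tr_seconds=tr)


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(100)
        ts = make_ts((5.0 + 0.2 * t)[:, None])
        out = detrend_linear(ts)
        assert np.abs(out.data).max() < 1e-10

    def test_output_has_zero_slope_and_mean(self, rng):
        t = np.arange(150)
        ts = make_ts(np.sin(0.3 * t)[:, None] + 0.05 * t[:, None])
        out = detrend_linear(ts).data[:, 0]
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 1e-12
        assert abs(out.mean()) < 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal((80, 3))
        t = np.arange(80, dtype=float)
        design = np.column_stack([np.ones(80), t])
        expected = ols_residuals(y, design)
        out = detrend_linear(make_ts(y)).data
        np.testing.assert_allclose(out, expected, atol=1e-8)
        # residuals orthogonal to [1, t]
        assert np.abs(design.T @ out).max() < 1e-8


class TestBandpass:
    def _ratio(self, freq_hz, tr=2.0, n=230):
        # RMS out/in on the central segment (the forward-backward pass has
        # start-up transients at the series ends)
        t = np.arange(n) * tr
        sig = np.sin(2 * np.pi * freq_hz * t)
        out = bandpass_filter(make_ts(sig[:, None], tr)).data[:, 0]
        mid = slice(30, n - 30)
        return np.sqrt(np.mean(out[mid]**2)) / np.sqrt(np.mean(sig[mid]**2))

    def test_passband_preserved(self):
        assert self._ratio(0.04) >= 0.9

    def test_stopband_attenuated(self):
        assert self._ratio(0.2) <= 0.1

    def test_dc_rejected(self):
        out = bandpass_filter(make_ts(np.full((230, 1), 7.0))).data
        assert np.abs(out).max() < 1e-6

    def test_high_cut_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(make_ts(np.zeros((50, 1))), high_hz=0.3)


class TestFriston24:
    def test_zero_motion_all_zero(self):
        out = friston24(MotionParams("s", np.zeros((30, 6))))
        assert out.shape == (30, 24)
        assert np.all(out == 0)

    def test_positional_bookkeeping(self):
        # single nonzero at (k, j) appears at (k,j), (k,j+6), (k+1,j+12), (k+1,j+18)
        k, j, value = 4, 2, 0.5
        data = np.zeros((10, 6))
        data[k, j] = value
        out = friston24(MotionParams("s", data))
        expected = np.zeros((10, 24))
        expected[k, j] = value
        expected[k, j + 6] = value**2
        expected[k + 1, j + 12] = value
        expected[k + 1, j + 18] = value**2
        np.testing.assert_array_equal(out, expected)

    def test_constant_ones(self):
        out = friston24(MotionParams("s", np.ones((5, 6))))
        assert np.all(out[1:] == 1.0)
        assert np.all(out[0, :12] == 1.0)
        assert np.all(out[0, 12:] == 0.0)


class TestRegressNuisance:
    def test_self_regression_annihilates(self, rng):
        y = rng.standard_normal(60)
        out = regress_nuisance(make_ts(y[:, None]), y[:, None])
        assert np.abs(out.data).max() < 1e-10

    def test_orthogonal_nuisance_only_demeans(self, rng):
        t = np.arange(64)
        signal = np.cos(2 * np.pi * t / 8)
        nuisance = np.sin(2 * np.pi * t / 8)[:, None]  # orthogonal to signal
        out = regress_nuisance(make_ts(signal[:, None]), nuisance).data[:, 0]
        np.testing.assert_allclose(out, signal - signal.mean(), atol=1e-10)

    def test_matches_ols_oracle_and_orthogonality(self, rng):
        y = rng.standard_normal((70, 4))
        nuisance = rng.standard_normal((70, 5))
        design = np.column_stack([np.ones(70), nuisance])
        expected = ols_residuals(y, design)
        out = regress_nuisance(make_ts(y), nuisance).data
        np.testing.assert_allclose(out, expected, atol=1e-8)
        rel = np.abs(design.T @ out) / np.abs(design).sum(axis=0)[:, None]
        assert rel.max() < 1e-6

    def test_rank_deficient_nuisance_handled(self, rng):
        y = rng.standard_normal((40, 2))
        col = rng.standard_normal(40)
        nuisance = np.column_stack([col, col, 2 * col])  # rank 1
        out = regress_nuisance(make_ts(y), nuisance).data
        assert np.all(np.isfinite(out))
        assert np.abs(out.T @ col).max() < 1e-6


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = framewise_displacement(MotionParams("s", np.zeros((20, 6))))
        assert np.all(fd.fd == 0)
        assert fd.fd_max == fd.fd_mean == fd.fd_rms == 0.0

    def test_translation_step(self):
        data = np.zeros((10, 6))
        data[5:, 0] = 1.0  # 1 mm x-step at frame 5
        fd = framewise_displacement(MotionParams("s", data))
        expected = np.zeros(10)
        expected[5] = 1.0
        np.testing.assert_allclose(fd.fd, expected)

    def test_rotation_step_scaled_by_head_radius(self):
        data = np.zeros((8, 6))
        data[3:, 4] = 0.02  # 0.02 rad step -> 0.02 * 50 = 1.0 mm
        fd = framewise_displacement(MotionParams("s", data))
        assert fd.fd[3] == pytest.approx(1.0)
        assert fd.fd_max == pytest.approx(1.0)


class TestMotionExclusion:
    def test_below_limits_kept(self):
        data = np.zeros((10, 6))
        data[4, 1] = 1.9
        data[6, 5] = np.radians(1.9)
        assert not motion_exclusion(MotionParams("s", data)).exclude

    def test_translation_above_limit(self):
        data = np.zeros((10, 6))
        data[7, 2] = 2.1
        result = motion_exclusion(MotionParams("s", data))
        assert result.exclude
        assert "z" in result.reason and "frame 7" in result.reason

    def test_rotation_in_radians_converted(self):
        data = np.zeros((10, 6))
        data[2, 3] = 0.04  # ~2.29 degrees
        result = motion_exclusion(MotionParams("s", data))
        assert result.exclude
        assert "rotation" in result.reason


class TestPipelineProperties:
    def test_cleaning_is_linear(self, rng):
        x = rng.standard_normal((120, 3))
        y = rng.standard_normal((120, 3))
        nuisance = rng.standard_normal((120, 4))
        out_sum = clean_timeseries(make_ts(x + y), nuisance).data
        out_parts = (clean_timeseries(make_ts(x), nuisance).data
                     + clean_timeseries(make_ts(y), nuisance).data)
        np.testing.assert_allclose(out_sum, out_parts, atol=1e-8)

    def test_stage_order_is_fixed(self, rng):
        # detrend -> band-pass -> regression differs from the reversed order,
        # and clean_timeseries follows the former
        x = rng.standard_normal((150, 2)) + np.arange(150)[:, None] * 0.1
        nuisance = rng.standard_normal((150, 3))
        ts = make_ts(x)
        canonical = regress_nuisance(
            bandpass_filter(detrend_linear(ts)), nuisance).data
        reversed_order = bandpass_filter(
            detrend_linear(regress_nuisance(ts, nuisance))).data
        np.testing.assert_allclose(clean_timeseries(ts, nuisance).data,
                                   canonical, atol=1e-10)
        assert not np.allclose(canonical, reversed_order, atol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_detrend_idempotent(self, seed):
        data = np.random.default_rng(seed).standard_normal((40, 2))
        once = detrend_linear(make_ts(data)).data
        twice = detrend_linear(make_ts(once)).data
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_signal_cleaner_transformer_api(self, rng):
        from sklearn.base import clone

        ts = make_ts(rng.standard_normal((120, 4)))
        mp = MotionParams("s", rng.standard_normal((120, 6)) * 0.01)
        cleaner = SignalCleaner(low_hz=0.01, high_hz=0.08)
        assert clone(cleaner).get_params()["low_hz"] == 0.01
        out = cleaner.fit_transform((ts, mp))
        expected = clean_timeseries(ts, friston24(mp)).data
        np.testing.assert_allclose(out.data, expected, atol=1e-10)
        out_list = cleaner.transform([ts, (ts, mp)])
        assert len(out_list) == 2
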