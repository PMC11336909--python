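"""Relative-change series, ROI statistics, stimulation-paradigm summaries,
and lagged cross-correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from fuspa.hemodynamics import (
    CrossCorrResult,
    RelativeSeries,
    StimulusParadigm,
    TimeSeries,
    crosscorr_map,
    paradigm_summary,
    relative_change,
    relative_change_stack,
    roi_pair_crosscorr,
    roi_timecourse,
)


def step_series(baseline, peak, n_base=10, n_peak=5):
    return TimeSeries(np.concatenate([np.full(n_base, baseline), np.full(n_peak, peak)]))


class TestRelativeChange:
    @pytest.mark.parametrize(
        "baseline,peak,expected_pct",
        [
            (9.5, 12.5, 31.6),   # artery, first cortical ROI
            (9.0, 11.3, 25.6),   # artery, second cortical ROI
            (6.0, 11.5, 91.7),   # vein, first cortical ROI
            (4.5, 10.0, 122.2),  # vein, second cortical ROI
        ],
    )
    def test_printed_baseline_peak_pairs(self, baseline, peak, expected_pct):
        rel = relative_change(step_series(baseline, peak))
        assert rel.percent[-1] == pytest.approx(expected_pct, abs=0.05)
        assert np.allclose(rel.percent[:10], 0.0)

    def test_constant_series_is_zero_everywhere(self):
        rel = relative_change(TimeSeries(np.full(20, 3.7)))
        assert np.allclose(rel.percent, 0.0)

    def test_zero_baseline_flagged_undefined(self):
        rel = relative_change(TimeSeries(np.concatenate([np.zeros(10), np.ones(5)])))
        assert np.all(np.isnan(rel.percent))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            relative_change(TimeSeries(np.ones(5), baseline_n=10))

    @given(scale=st.floats(0.1, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_global_scaling(self, scale):
        values = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 1.0, 2.0, 1.5, 3.0, 2.5, 5.0, 6.0])
        a = relative_change(TimeSeries(values))
        b = relative_change(TimeSeries(scale * values))
        assert np.allclose(a.percent, b.percent, rtol=1e-9)

    def test_stack_version_matches_per_pixel(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(1, 2, size=(15, 3, 3))
        rel = relative_change_stack(stack)
        one = relative_change(TimeSeries(stack[:, 1, 2])).percent
        assert np.allclose(rel[:, 1, 2], one)


class TestRoiTimecourse:
    def test_single_pixel_mask_returns_its_trace(self):
        stack = np.random.default_rng(1).normal(size=(12, 4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 3] = True
        ts, std = roi_timecourse(stack, mask)
        assert np.allclose(ts.values, stack[:, 2, 3])
        assert np.allclose(std, 0.0)

    def test_two_pixel_closed_form(self):
        stack = np.zeros((5, 1, 2))
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 2.0, 0.0, 8.0, 5.0])
        stack[:, 0, 0] = a
        stack[:, 0, 1] = b
        ts, std = roi_timecourse(stack, np.ones((1, 2), dtype=bool))
        assert np.allclose(ts.values, (a + b) / 2)
        assert np.allclose(std, np.abs(a - b) / 2)  # population std for n = 2

    def test_uniform_stack_has_zero_std(self):
        stack = np.ones((6, 3, 3)) * 4.2
        _, std = roi_timecourse(stack, np.ones((3, 3), dtype=bool))
        assert np.allclose(std, 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            roi_timecourse(np.ones((4, 2, 2)), np.zeros((2, 2), dtype=bool))


def smooth_noise(n, seed, sigma=4):
    return ndimage.gaussian_filter1d(np.random.default_rng(seed).normal(size=n), sigma)


class TestCrossCorrelation:
    def test_self_correlation_is_one_at_lag_zero(self):
        ref = smooth_noise(100, 2)
        stack = np.broadcast_to(ref[:, None, None], (100, 2, 2)).copy()
        mask = np.ones((2, 2), dtype=bool)
        res = crosscorr_map(stack, mask, max_lag=5, frame_period_s=0.71)
        lag0 = np.flatnonzero(res.lags_frames == 0)[0]
        assert np.allclose(res.r[lag0], 1.0)

    def test_exact_shift_detected(self):
        ref = smooth_noise(120, 3)
        stack = np.zeros((120, 1, 2))
        stack[:, 0, 0] = ref
        stack[2:, 0, 1] = ref[:-2]  # voxel delayed by +2 frames
        stack[:2, 0, 1] = ref[0]
        mask = np.zeros((1, 2), dtype=bool)
        mask[0, 0] = True
        res = crosscorr_map(stack, mask, max_lag=6, frame_period_s=0.71)
        voxel_r = res.r[:, 0, 1]
        assert res.lags_frames[np.argmax(voxel_r)] == 2
        assert voxel_r.max() == pytest.approx(1.0, abs=1e-9)

    def test_anti_correlated_voxel(self):
        ref = smooth_noise(80, 4)
        stack = np.zeros((80, 1, 2))
        stack[:, 0, 0] = ref
        stack[:, 0, 1] = -ref
        mask = np.zeros((1, 2), dtype=bool)
        mask[0, 0] = True
        res = crosscorr_map(stack, mask, max_lag=3, frame_period_s=0.71)
        lag0 = np.flatnonzero(res.lags_frames == 0)[0]
        assert res.r[lag0, 0, 1] == pytest.approx(-1.0)

    def test_zero_variance_voxel_masked(self):
        ref = smooth_noise(60, 5)
        stack = np.zeros((60, 1, 2))
        stack[:, 0, 0] = ref
        stack[:, 0, 1] = 3.14
        mask = np.zeros((1, 2), dtype=bool)
        mask[0, 0] = True
        res = crosscorr_map(stack, mask, max_lag=2, frame_period_s=0.71)
        assert np.all(np.isnan(res.r[:, 0, 1]))

    def test_symmetry_between_rois(self):
        rng = np.random.default_rng(6)
        stack = rng.normal(size=(60, 2, 2))
        a = np.zeros((2, 2), dtype=bool); a[0, 0] = True
        b = np.zeros((2, 2), dtype=bool); b[1, 1] = True
        ab = roi_pair_crosscorr(stack, a, b, max_lag=4)
        ba = roi_pair_crosscorr(stack, b, a, max_lag=4)
        assert np.allclose(ab.r, ba.r[::-1], atol=1e-12)

    def test_all_r_bounded_by_one(self):
        rng = np.random.default_rng(7)
        stack = rng.normal(size=(50, 4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2] = True
        res = crosscorr_map(stack, mask, max_lag=8)
        assert np.nanmax(np.abs(res.r)) <= 1.0 + 1e-12

    def test_half_period_shifted_sines(self):
        n, period = 96, 16
        t = np.arange(n)
        s1 = np.sin(2 * np.pi * t / period)
        s2 = np.sin(2 * np.pi * (t - period / 2) / period)  # anti-phase
        stack = np.zeros((n, 1, 2))
        stack[:, 0, 0] = s1
        stack[:, 0, 1] = s2
        a = np.zeros((1, 2), dtype=bool); a[0, 0] = True
        b = np.zeros((1, 2), dtype=bool); b[0, 1] = True
        res = roi_pair_crosscorr(stack, a, b, max_lag=period // 2, frame_period_s=1.0)
        lag0 = np.flatnonzero(res.lags_frames == 0)[0]
        assert res.r[lag0] == pytest.approx(-1.0, abs=1e-6)
        assert res.r[-1] == pytest.approx(1.0, abs=0.01)  # lag = half period

    def test_delayed_antiphase_vein_trough_at_1_42_s(self):
        """A vein series built as the negated cortical series delayed by two
        0.71 s frames decorrelates most strongly at +1.42 s lag."""
        ref = smooth_noise(200, 8)
        vein = np.empty_like(ref)
        vein[2:] = -ref[:-2]
        vein[:2] = -ref[0]
        stack = np.zeros((200, 2, 2))
        stack[:, 0, :] = ref[:, None]
        stack[:, 1, :] = vein[:, None]
        cortex = np.zeros((2, 2), dtype=bool); cortex[0] = True
        vroi = np.zeros((2, 2), dtype=bool); vroi[1] = True
        res = roi_pair_crosscorr(stack, cortex, vroi, max_lag=10, frame_period_s=0.71)
        assert res.trough_lag_s == pytest.approx(1.42, abs=1e-9)
        assert res.r.min() == pytest.approx(-1.0, abs=1e-9)


class TestParadigmSummary:
    def make_rel(self, values, dt=3.3):
        return RelativeSeries(np.asarray(values, dtype=float), 0.0, dt, 10)

    def test_step_response_peak_equals_amplitude(self):
        dt = 4.0
        paradigm = StimulusParadigm(baseline_s=40, stimulus_s=40, post_s=40)
        series = np.concatenate([np.zeros(10), np.full(20, 25.0)])
        out = paradigm_summary(self.make_rel(series, dt), paradigm)
        assert out["stimulus_mean"] == pytest.approx(25.0)
        assert out["peak_value"] == pytest.approx(25.0)

    def test_flat_series_equal_windows(self):
        paradigm = StimulusParadigm(baseline_s=10, stimulus_s=10, post_s=10)
        out = paradigm_summary(self.make_rel(np.full(30, 7.0), 1.0), paradigm)
        assert out["baseline_mean"] == out["stimulus_mean"] == out["post_mean"] == 7.0

    def test_ramp_peaks_at_end_of_stimulus(self):
        dt = 1.0
        paradigm = StimulusParadigm(baseline_s=10, stimulus_s=10, post_s=10)
        stim = np.linspace(0, 10, 10)
        series = np.concatenate([np.zeros(10), stim, stim[-1] - np.linspace(0, 10, 10)])
        out = paradigm_summary(self.make_rel(series, dt), paradigm)
        assert out["peak_time_s"] == pytest.approx(9.0)

    def test_short_series_rejected(self):
        paradigm = StimulusParadigm()
        with pytest.raises(ValueError):
            paradigm_summary(self.make_rel(np.zeros(10), 3.3), paradigm)
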