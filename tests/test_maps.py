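"""Functional maps: response timing, Fourier tonotopy, vessel masking and
neurovascular correlation maps."""

import numpy as np
import pytest

from nvckit import maps
from nvckit import synthetic as syn
from nvckit import traces
from nvckit.datatypes import FrameStack, StimulusProtocol


def protocol_for(onsets, isi):
    return StimulusProtocol(np.asarray(onsets, float), duration_s=0.2,
                            inter_stimulus_interval_s=isi)


class TestResponseMaps:
    fs = 10.0

    def build_stack(self, delays, amp=1.0):
        """Every pixel shares one response shape, delayed per pixel."""
        ny, nx = delays.shape
        n_trials, isi = 3, 6.0
        n = int((1.0 + n_trials * isi) * self.fs)
        onsets = [1.0 + isi * k for k in range(n_trials)]
        kernel = syn.gamma_hrf(self.fs, peak_s=1.0)
        data = np.zeros((n, ny, nx))
        for onset in onsets:
            for iy in range(ny):
                for ix in range(nx):
                    i = int(round((onset + delays[iy, ix]) * self.fs))
                    seg = kernel[: n - i]
                    data[i:i + seg.size, iy, ix] += amp * seg
        return FrameStack(data, self.fs), onsets, isi

    def test_peak_time_map_tracks_injected_delay(self):
        delays = np.array([[0.0, 0.3], [0.6, 0.9]])
        stack, onsets, isi = self.build_stack(delays)
        rm = maps.response_maps(stack, protocol_for(onsets, isi),
                                pre_s=1.0, post_s=4.0)
        base_peak = rm.peak_time_s[0, 0]
        np.testing.assert_allclose(rm.peak_time_s - base_peak, delays,
                                   atol=1e-9)

    def test_amplitude_map_proportional_to_gain(self):
        delays = np.zeros((2, 2))
        stack1, onsets, isi = self.build_stack(delays, amp=1.0)
        stack2, _, _ = self.build_stack(delays, amp=2.5)
        p = protocol_for(onsets, isi)
        rm1 = maps.response_maps(stack1, p, 1.0, 4.0)
        rm2 = maps.response_maps(stack2, p, 1.0, 4.0)
        np.testing.assert_allclose(rm2.amplitude / rm1.amplitude, 2.5,
                                   rtol=1e-6)

    def test_noise_only_stack_all_invalid(self, rng):
        noise_sd = 0.1
        data = rng.normal(0, noise_sd, (100, 4, 4))
        stack = FrameStack(data - data.min() + 1.0, self.fs)
        rm = maps.response_maps(stack, protocol_for([1.0, 4.0, 7.0], 3.0),
                                1.0, 2.0, min_amplitude=3 * noise_sd)
        assert not rm.valid_mask.any()

    def test_map_equals_per_pixel_trace_metrics(self):
        """Map values must be bit-identical to response_metrics applied to
        the extracted single-pixel trace."""
        delays = np.array([[0.0, 0.4]])
        stack, onsets, isi = self.build_stack(delays)
        rm = maps.response_maps(stack, protocol_for(onsets, isi), 1.0, 4.0)
        npre = int(round(1.0 * self.fs))
        for iy in range(1):
            for ix in range(2):
                ep, _, _ = traces.epoch_traces(stack.data[:, iy, ix], self.fs,
                                               onsets, 1.0, 4.0)
                m = traces.response_metrics(ep.mean(axis=0), np.arange(npre),
                                            self.fs, stimulus_time_s=1.0)
                assert rm.amplitude[iy, ix] == m.amplitude
                assert rm.peak_time_s[iy, ix] == m.peak_time_s
                assert rm.onset_time_s[iy, ix] == m.onset_time_s

    def test_onset_not_after_peak(self):
        delays = np.array([[0.0, 0.5]])
        stack, onsets, isi = self.build_stack(delays)
        rm = maps.response_maps(stack, protocol_for(onsets, isi), 1.0, 4.0)
        ok = rm.valid_mask
        assert np.all(rm.onset_time_s[ok] <= rm.peak_time_s[ok])


class TestFourierTonalMap:
    tones = (3.0, 6.0, 12.0, 24.0, 48.0)

    def test_zero_noise_preferred_tone_exact(self, rng):
        phase = rng.uniform(0, 2 * np.pi, (12, 12))
        stack, truth = syn.gen_tonal_session(phase, n_sweeps=3, seed=5)
        tm = maps.fourier_tonal_map(stack, 15.0, self.tones)
        period_frames = int(15.0 * truth.params["frame_rate"])
        true_idx = truth.params["offset_frames"] * len(self.tones) // period_frames
        expected = np.asarray(self.tones)[true_idx]
        assert (tm.preferred_tone_khz == expected).all()

    def test_amplitude_scaling_leaves_phase_fixed(self, rng):
        phase = rng.uniform(0, 2 * np.pi, (6, 6))
        stack, _ = syn.gen_tonal_session(phase, n_sweeps=2, seed=6)
        tm1 = maps.fourier_tonal_map(stack, 15.0, self.tones)
        scaled = FrameStack(stack.data * 9.0, stack.frame_rate)
        tm2 = maps.fourier_tonal_map(scaled, 15.0, self.tones)
        np.testing.assert_allclose(tm1.phase_rad, tm2.phase_rad, atol=1e-12)
        np.testing.assert_array_equal(tm1.preferred_tone_khz,
                                      tm2.preferred_tone_khz)

    def test_constant_pixel_zero_magnitude(self):
        stack, _ = syn.gen_tonal_session(np.zeros((4, 4)), n_sweeps=2, seed=0,
                                         amplitude_map=np.zeros((4, 4)))
        tm = maps.fourier_tonal_map(stack, 15.0, self.tones)
        np.testing.assert_allclose(tm.magnitude, 0.0, atol=1e-12)

    def test_phase_wraps_identically(self):
        stack1, _ = syn.gen_tonal_session(np.full((3, 3), 1.0), n_sweeps=2, seed=1)
        stack2, _ = syn.gen_tonal_session(np.full((3, 3), 1.0 + 2 * np.pi),
                                          n_sweeps=2, seed=1)
        tm1 = maps.fourier_tonal_map(stack1, 15.0, self.tones)
        tm2 = maps.fourier_tonal_map(stack2, 15.0, self.tones)
        np.testing.assert_allclose(tm1.phase_rad, tm2.phase_rad, atol=1e-12)

    def test_recording_delay_shifts_phase_equivariantly(self, rng):
        phase = rng.uniform(0.5, 2 * np.pi - 0.5, (5, 5))
        stack, truth = syn.gen_tonal_session(phase, n_sweeps=4, seed=7)
        shift_frames = 12
        period = 15.0
        fs = truth.params["frame_rate"]
        delayed = FrameStack(np.roll(stack.data, shift_frames, axis=0), fs)
        tm0 = maps.fourier_tonal_map(stack, period, self.tones)
        tm1 = maps.fourier_tonal_map(delayed, period, self.tones)
        dphi = 2 * np.pi * (shift_frames / fs) / period
        circ_diff = np.angle(np.exp(1j * (tm1.phase_rad - tm0.phase_rad + dphi)))
        np.testing.assert_allclose(circ_diff, 0.0, atol=1e-9)

    def test_short_recording_rejected(self):
        stack, _ = syn.gen_tonal_session(np.zeros((3, 3)), n_sweeps=2, seed=0)
        short = FrameStack(stack.data[:200], stack.frame_rate)
        with pytest.raises(ValueError, match="2 sweep"):
            maps.fourier_tonal_map(short, 15.0, self.tones)


class TestVesselMask:
    def test_drawn_dark_tubes_recovered(self, rng):
        img = np.full((64, 64), 100.0)
        truth = np.zeros((64, 64), bool)
        truth[:, 20:24] = True
        truth[30:34, :] = True
        img[truth] = 20.0
        mask = maps.vessel_mask(img)
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.9

    def test_constant_image_empty_mask(self):
        assert not maps.vessel_mask(np.full((32, 32), 50.0)).any()

    def test_bright_mode_on_inverted_contrast(self):
        img = np.full((32, 32), 100.0)
        img[:, 10:14] = 20.0
        inverted = 120.0 - img
        np.testing.assert_array_equal(maps.vessel_mask(img, "dark"),
                                      maps.vessel_mask(inverted, "bright"))

    def test_degenerate_threshold_rejected(self, rng):
        img = np.exp(rng.normal(0, 0.001, (16, 16)))
        img[0, 0] = 100.0  # everything else "dark"
        with pytest.raises(ValueError, match="degenerate"):
            maps.vessel_mask(img)


class TestNvcm:
    def test_shifted_scaled_copy_perfect_correlation(self, rng):
        """Pixels that are affine copies of the trace at any shift within the
        lag window must give r = 1 and the exact shift."""
        fs, n = 10.0, 400
        trace = np.convolve(rng.standard_normal(n), np.ones(5) / 5, "same")
        shifts = [0, 3, 17, 50]  # frames, up to the ±5 s window
        data = np.zeros((n, 2, 2))
        for k, (iy, ix) in zip(shifts, [(0, 0), (0, 1), (1, 0), (1, 1)]):
            data[:, iy, ix] = 2.5 * np.roll(trace, k) + 1.0
        res = maps.nvcm(FrameStack(data, fs), trace, lag_window_s=5.0)
        for k, (iy, ix) in zip(shifts, [(0, 0), (0, 1), (1, 0), (1, 1)]):
            assert res.norm_xcorr[iy, ix] == pytest.approx(1.0, abs=1e-6)
            assert res.lag_time_s[iy, ix] == pytest.approx(k / fs, abs=1e-9)

    def test_independent_noise_pixel_low_correlation(self, rng):
        fs, n = 10.0, 1000
        trace = rng.standard_normal(n)
        data = rng.standard_normal((n, 3, 3))
        res = maps.nvcm(FrameStack(data, fs), trace, lag_window_s=1.0)
        # max-over-lags inflates the null; 4/sqrt(n) bounds it comfortably
        assert np.nanmax(np.abs(res.norm_xcorr)) < 4 / np.sqrt(n) * 2.5

    def test_session_lag_recovery(self):
        dff, dhbt, truth = syn.gen_nvc_session(seed=2, lag_s=1.5, noise_sd=0.0)
        reg = maps.region_traces(dff, truth.params["region_masks"])
        res = maps.nvcm(dhbt, reg.traces[1], lag_window_s=5.0)
        m1 = truth.params["region_masks"][1]
        fs = truth.params["frame_rate"]
        assert abs(np.nanmean(res.lag_time_s[m1]) - truth.params["lag_s"]) \
            <= 1.0 / fs

    def test_vessel_pixels_masked_nan(self, rng):
        fs, n = 10.0, 200
        trace = rng.standard_normal(n)
        data = np.tile(trace[:, None, None], (1, 4, 4))
        vm = np.zeros((4, 4), bool)
        vm[0, :] = True
        res = maps.nvcm(FrameStack(data, fs), trace, vessel_mask=vm)
        assert np.isnan(res.norm_xcorr[0]).all()
        assert np.isfinite(res.norm_xcorr[1:]).all()

    def test_zero_coupling_session_near_zero_correlation(self):
        dff, dhbt, truth = syn.gen_nvc_session(seed=3, gain=0.0, noise_sd=0.05,
                                               n_frames=500)
        reg = maps.region_traces(dff, truth.params["region_masks"])
        res = maps.nvcm(dhbt, reg.traces[1], lag_window_s=2.0)
        m1 = truth.params["region_masks"][1]
        assert np.nanmean(np.abs(res.norm_xcorr[m1])) < 3 / np.sqrt(500) * 3

    def test_zero_variance_trace_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            maps.nvcm(FrameStack(np.random.default_rng(0).normal(size=(50, 2, 2)),
                                 10.0), np.ones(50))


class TestRegionTraces:
    def test_single_pixel_region(self, rng):
        data = rng.standard_normal((30, 4, 4))
        mask = np.zeros((4, 4), bool)
        mask[2, 3] = True
        ts = maps.region_traces(FrameStack(data, 10.0), {1: mask})
        np.testing.assert_array_equal(ts.traces[1], data[:, 2, 3])

    def test_uniform_signal_region_returns_signal(self, rng):
        s = rng.standard_normal(40)
        data = np.tile(s[:, None, None], (1, 3, 3))
        ts = maps.region_traces(FrameStack(data, 10.0),
                                {1: np.ones((3, 3), bool)})
        np.testing.assert_allclose(ts.traces[1], s, atol=1e-12)

    def test_orthogonal_signals_stay_uncorrelated(self):
        n, fs = 600, 10.0
        t = np.arange(n) / fs
        s1, s2 = np.sin(2 * np.pi * 0.25 * t), np.cos(2 * np.pi * 0.25 * t)
        data = np.zeros((n, 2, 4))
        data[:, 0, :2] = s1[:, None]
        data[:, 1, 2:] = s2[:, None]
        m1 = np.zeros((2, 4), bool)
        m1[0, :2] = True
        m2 = np.zeros((2, 4), bool)
        m2[1, 2:] = True
        ts = maps.region_traces(FrameStack(data, fs), {1: m1, 2: m2})
        r = np.corrcoef(ts.traces[1], ts.traces[2])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_overlapping_masks_rejected(self):
        m = np.ones((2, 2), bool)
        with pytest.raises(ValueError, match="disjoint"):
            maps.region_traces(FrameStack(np.ones((5, 2, 2)), 10.0),
                               {1: m, 2: m})

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            maps.region_traces(FrameStack(np.ones((5, 2, 2)), 10.0),
                               {1: np.zeros((2, 2), bool)})
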