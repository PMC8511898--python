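"""Calcium trace chain: extraction, corrections, ΔF/F, denoising, trial
statistics and response metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvckit import hemodynamics as hemo
from nvckit import synthetic as syn
from nvckit import traces
from nvckit.datatypes import FrameStack, RoiSet


class TestExtractRoiTraces:
    def test_single_pixel_roi_returns_pixel_series(self, rng):
        data = rng.uniform(0, 100, (20, 8, 8))
        label = np.zeros((8, 8), dtype=np.int32)
        label[3, 4] = 1
        ts = traces.extract_roi_traces(FrameStack(data, 10.0),
                                       RoiSet(label, {1: "soma"}))
        np.testing.assert_array_equal(ts.traces[1], data[:, 3, 4])

    def test_two_pixel_roi_averages(self, rng):
        data = rng.uniform(0, 100, (10, 4, 4))
        label = np.zeros((4, 4), dtype=np.int32)
        label[0, 0] = label[1, 1] = 1
        ts = traces.extract_roi_traces(FrameStack(data, 10.0),
                                       RoiSet(label, {1: "soma"}))
        np.testing.assert_allclose(ts.traces[1],
                                   (data[:, 0, 0] + data[:, 1, 1]) / 2)

    def test_session_soma_trace_matches_truth_contamination(self):
        fluor, _, roi, truth = syn.gen_calcium_session(seed=2, noise_sd=0.0)
        ts = traces.extract_roi_traces(fluor, roi)
        sid = truth.params["soma_ids"][0]
        nid = truth.params["neuropil_ids"][0]
        r = truth.params["neuropil_r"]
        # extracted soma trace must carry exactly F_true + r*F_neuropil
        # (times the attenuation), i.e. subtracting r*neuropil recovers a
        # trace proportional to 1 + true dF/F
        corrected = traces.neuropil_correct(ts.traces[sid], ts.traces[nid], r)
        atten = truth.params["attenuation"]
        ratio = corrected / atten
        dff = ratio / ratio[0] - 1.0
        np.testing.assert_allclose(dff, truth.params["true_dff"][sid], atol=1e-10)


class TestNeuropilCorrect:
    def test_zero_neuropil_is_identity(self, rng):
        tr = rng.uniform(size=30)
        np.testing.assert_array_equal(
            traces.neuropil_correct(tr, np.zeros(30), 0.7), tr)

    def test_r_zero_is_identity(self, rng):
        tr, npil = rng.uniform(size=30), rng.uniform(size=30)
        np.testing.assert_array_equal(traces.neuropil_correct(tr, npil, 0.0), tr)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.99))
    def test_contamination_roundtrip(self, r):
        rng = np.random.default_rng(3)
        f_true, f_np = rng.uniform(1, 2, 50), rng.uniform(1, 2, 50)
        measured = f_true + r * f_np
        np.testing.assert_allclose(traces.neuropil_correct(measured, f_np, r),
                                   f_true, atol=1e-12)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            traces.neuropil_correct(np.ones(5), np.ones(5), 1.0)


class TestComputeDff:
    def test_constant_trace_zero_dff(self):
        out = traces.compute_dff(np.full(50, 80.0), 10.0, [2.0])
        np.testing.assert_allclose(out, 0.0)

    def test_half_rise_gives_half_dff(self):
        tr = np.full(50, 100.0)
        tr[30] = 150.0
        out = traces.compute_dff(tr, 10.0, [2.0])
        assert out[30] == pytest.approx(0.5)

    def test_gain_invariance(self, rng):
        tr = rng.uniform(50, 150, 60)
        a = traces.compute_dff(tr, 10.0, [2.0])
        b = traces.compute_dff(tr * 37.5, 10.0, [2.0])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_onset_without_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            traces.compute_dff(np.ones(50), 10.0, [0.5])


class TestEwma:
    def test_constant_input_unchanged(self):
        out = traces.ewma_filter(np.full(100, 3.3), 0.2, 10.0)
        np.testing.assert_allclose(out, 3.3)

    def test_impulse_decays_geometrically(self):
        x = np.zeros(30)
        x[0] = 1.0
        tau, fs = 0.5, 10.0
        out = traces.ewma_filter(x, tau, fs)
        lam = np.exp(-1.0 / (tau * fs))
        ratios = out[2:10] / out[1:9]
        np.testing.assert_allclose(ratios, lam, rtol=1e-10)

    def test_white_noise_variance_reduction(self, rng):
        tau_samples = 10.0
        fs = 1.0
        lam = np.exp(-1.0 / tau_samples)
        x = rng.standard_normal(200_00)
        y = traces.ewma_filter(x, tau_samples, fs)
        expected = (1 - lam) / (1 + lam)  # AR(1) steady-state variance gain
        assert y[1000:].var() / x.var() == pytest.approx(expected, rel=0.1)


class TestTrialAverage:
    def test_identical_trials_mean_equals_trial_sem_zero(self):
        fs = 10.0
        one = np.concatenate([np.zeros(10), np.ones(10), np.zeros(20)])
        tr = np.tile(one, 4)
        onsets = [1.0 + 4.0 * k for k in range(4)]
        out = traces.trial_average(tr, fs, onsets, pre_s=1.0, post_s=3.0)
        np.testing.assert_allclose(out.traces[0], one)
        np.testing.assert_allclose(out.trial_sem[0], 0.0, atol=1e-12)

    def test_antisymmetric_trials_average_to_zero(self, rng):
        fs = 10.0
        x = rng.standard_normal(40)
        tr = np.concatenate([x, -x])
        out = traces.trial_average(tr, fs, [1.0, 5.0], pre_s=1.0, post_s=3.0)
        np.testing.assert_allclose(out.traces[0], 0.0, atol=1e-12)

    def test_sem_scales_inverse_sqrt_n(self, rng):
        fs, sd = 10.0, 1.0
        sems = {}
        for n in (4, 16):
            tr = rng.normal(0, sd, n * 40)
            onsets = [1.0 + 4.0 * k for k in range(n)]
            out = traces.trial_average(tr, fs, onsets, 1.0, 3.0)
            sems[n] = out.trial_sem[0].mean()
        assert sems[4] / sems[16] == pytest.approx(2.0, rel=0.2)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            traces.trial_average(np.ones(40), 10.0, [1.0], 1.0, 2.0)


class TestResponseMetrics:
    fs = 10.0

    def ramp(self, t0=1.0, slope=1.0, length=5.0):
        t = np.arange(0, length, 1 / self.fs)
        return np.clip((t - t0) * slope, 0, None)

    def test_ideal_ramp_onset_exact(self):
        m = traces.response_metrics(self.ramp(), np.arange(10), self.fs)
        assert m.onset_time_s == pytest.approx(1.0, abs=1e-9)
        assert m.classification == "responsive"

    def test_amplitude_scaling_leaves_times_fixed(self):
        m1 = traces.response_metrics(self.ramp(), np.arange(10), self.fs)
        m5 = traces.response_metrics(5 * self.ramp(), np.arange(10), self.fs)
        assert m5.onset_time_s == pytest.approx(m1.onset_time_s, abs=1e-9)
        assert m5.peak_time_s == m1.peak_time_s
        assert m5.amplitude == pytest.approx(5 * m1.amplitude)

    def test_peak_time_is_argmax_of_gamma_response(self):
        t = np.arange(0, 8, 1 / self.fs)
        resp = np.concatenate([np.zeros(10), syn.gamma_hrf(self.fs, peak_s=1.5)])[:t.size]
        m = traces.response_metrics(resp, np.arange(10), self.fs)
        assert m.peak_time_s == pytest.approx((10 + 15) / self.fs)
        assert m.onset_time_s <= m.peak_time_s

    def test_flat_trace_classified_non_responsive(self):
        m = traces.response_metrics(np.zeros(50), np.arange(10), self.fs)
        assert m.classification == "non-responsive"
        assert np.isnan(m.peak_time_s)

    def test_off_response_with_polarity_flag(self):
        m = traces.response_metrics(-self.ramp(), np.arange(10), self.fs,
                                    polarity=-1)
        assert m.onset_time_s == pytest.approx(1.0, abs=1e-9)
        assert m.amplitude > 0

    def test_steep_step_uses_fallback_interpolation(self):
        y = np.concatenate([np.zeros(20), np.ones(20)])
        m = traces.response_metrics(y, np.arange(10), self.fs)
        assert m.fallback_interpolated
        assert np.isfinite(m.onset_time_s)


class TestFullChainRecovery:
    def test_zero_noise_event_amplitude_recovery(self):
        fluor, reflect, roi, truth = syn.gen_calcium_session(seed=9, noise_sd=0.0)
        fs = truth.params["frame_rate"]
        onsets = truth.params["event_times_s"]
        ts = traces.extract_roi_traces(fluor, roi)
        for sid, nid in zip(truth.params["soma_ids"], truth.params["neuropil_ids"]):
            corrected = traces.neuropil_correct(ts.traces[sid], ts.traces[nid],
                                                truth.params["neuropil_r"])
            dff_meas = traces.compute_dff(corrected, fs, onsets)
            r_trace = reflect.data[:, 0, 0]
            r_dff = traces.compute_dff(r_trace, fs, onsets)
            final = hemo.hemodynamic_correct(dff_meas + 1, r_dff + 1)
            np.testing.assert_allclose(final, truth.params["true_dff"][sid],
                                       atol=1e-10)
            epochs, _, _ = traces.epoch_traces(final, fs, onsets, 1.0, 3.0)
            amp = epochs.mean(axis=0).max()
            assert amp == pytest.approx(truth.params["event_amplitude"],
                                        rel=1e-6)
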