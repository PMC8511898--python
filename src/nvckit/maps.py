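"""Pixelwise functional maps: response timing, Fourier tonotopy, pial-vessel
masking and neurovascular correlation maps (NVCMs).

The NVCM answers "how does cortex-wide blood volume follow the activity of
one region?": for every non-vessel pixel, the cross-correlation between the
pixel's ΔHbT time course and a regional neuronal ΔF/F trace is maximized
over lags in a window (default ±5 s, comfortably bracketing hemodynamic
delays of 1–2 s). Three maps come out: the cross-covariance at the best
lag (XCorr), the Pearson coefficient there (NormXCorr), and the lag itself
(positive = hemodynamics follow neurons). Pial-vessel pixels carry their
own dynamics and are excluded (NaN).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .datatypes import (FrameStack, NVCMaps, ResponseMaps, StimulusProtocol,
                        TonalMap, TraceSet)
from .traces import epoch_traces, response_metrics

__all__ = [
    "response_maps",
    "fourier_tonal_map",
    "vessel_mask",
    "nvcm",
    "region_traces",
    "timing_histogram",
]


def response_maps(stack: FrameStack, protocol: StimulusProtocol,
                  pre_s: float = 1.0, post_s: float = 3.0,
                  min_amplitude: float = 0.0) -> ResponseMaps:
    """Per-pixel amplitude / peak-time / onset-time maps.

    Each pixel's time series is trial-averaged over the protocol's onsets
    and summarized with the same :func:`~nvckit.traces.response_metrics`
    used for ROI traces (map/trace consistency is exact by construction).
    Pixels with amplitude below ``min_amplitude`` are flagged invalid (NaN).
    Times are relative to the epoch start (stimulus at ``pre_s``).
    """
    fs = stack.frame_rate
    npre = int(round(pre_s * fs))
    ny, nx = stack.frame_shape
    flat = stack.data.reshape(stack.n_frames, -1)
    epochs, _, _ = epoch_traces(flat[:, 0], fs, protocol.onsets_s, pre_s, post_s)
    if epochs.shape[0] == 0:
        raise ValueError("no complete trials in the recording")
    pre_frames = np.arange(npre)
    amp = np.full(ny * nx, np.nan)
    pk = np.full(ny * nx, np.nan)
    on = np.full(ny * nx, np.nan)
    valid = np.zeros(ny * nx, dtype=bool)
    for p in range(ny * nx):
        ep, _, _ = epoch_traces(flat[:, p], fs, protocol.onsets_s, pre_s, post_s)
        mean = ep.mean(axis=0)
        m = response_metrics(mean, pre_frames, fs, stimulus_time_s=pre_s)
        if m.classification == "responsive" and m.amplitude >= min_amplitude:
            amp[p], pk[p], on[p] = m.amplitude, m.peak_time_s, m.onset_time_s
            valid[p] = True
    shape = (ny, nx)
    return ResponseMaps(amp.reshape(shape), pk.reshape(shape), on.reshape(shape),
                        valid.reshape(shape))


def fourier_tonal_map(stack: FrameStack, sweep_period_s: float,
                      tone_set_khz: Sequence[float],
                      phase_offset_s: float = 0.0) -> TonalMap:
    """Fourier tonotopy: per-pixel phase of the response at the sweep
    frequency maps to a preferred tone.

    The recording is trimmed to an integer number of sweep periods; the
    discrete Fourier coefficient at f = 1/period gives magnitude and phase
    per pixel. Phase is converted to a time within the sweep (after
    subtracting ``phase_offset_s`` of response delay) and assigned to the
    tone slot containing it (tones are presented in ascending order in
    equal slots).
    """
    fs = stack.frame_rate
    period_frames = int(round(sweep_period_s * fs))
    n_periods = stack.n_frames // period_frames
    if n_periods < 2:
        raise ValueError("recording must span at least 2 sweep periods")
    n_use = n_periods * period_frames
    if n_use < stack.n_frames:
        import logging
        logging.getLogger("nvckit").info(
            "fourier_tonal_map: trimming %d trailing frames", stack.n_frames - n_use)
    data = stack.data[:n_use]
    t = np.arange(n_use)
    basis = np.exp(-2j * np.pi * t / period_frames)
    coeff = np.tensordot(basis, data - data.mean(axis=0, keepdims=True), axes=(0, 0)) \
        / n_use
    magnitude = np.abs(coeff)
    # a response at sweep time t0 contributes phase −2π·t0/period
    phase = np.angle(coeff)
    sweep_time = np.mod(-phase / (2 * np.pi) * sweep_period_s - phase_offset_s,
                        sweep_period_s)
    # quantize to the frame grid before slot assignment so responses on a
    # slot boundary are not mis-binned by float round-off
    frame_est = np.mod(np.round(sweep_time * fs).astype(int), period_frames)
    n_tones = len(tone_set_khz)
    idx = np.minimum(frame_est * n_tones // period_frames, n_tones - 1)
    preferred = np.asarray(tone_set_khz, dtype=float)[idx]
    phase_wrapped = np.angle(np.exp(1j * phase))  # (−π, π]
    return TonalMap(phase_wrapped, magnitude, preferred, sweep_period_s)


def vessel_mask(baseline_image: np.ndarray, threshold_mode: str = "dark",
                closing_radius: int = 2, max_fraction: float = 0.8) -> np.ndarray:
    """Segment pial vessels in a baseline reflectance image.

    Vessels are strong absorbers (dark) under green illumination: Otsu
    thresholding on log-reflectance, then morphological closing. Pass
    ``threshold_mode='bright'`` for inverted-contrast inputs.
    """
    img = np.asarray(baseline_image, dtype=float)
    if np.any(img <= 0):
        raise ValueError("baseline image must be strictly positive")
    log_img = np.log(img)
    if np.ptp(log_img) == 0:
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(log_img)
    mask = log_img < thr if threshold_mode == "dark" else log_img > thr
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    frac = mask.mean()
    if frac > max_fraction:
        raise ValueError(f"vessel mask covers {frac:.0%} of the field "
                         "(degenerate threshold)")
    return mask


def _resample_linear(trace: np.ndarray, rate_from: float, rate_to: float,
                     n_to: int) -> np.ndarray:
    t_to = np.arange(n_to) / rate_to
    t_from = np.arange(trace.size) / rate_from
    return np.interp(t_to, t_from, trace)


def nvcm(dhbt_stack: FrameStack, regional_trace: np.ndarray,
         lag_window_s: float = 5.0,
         vessel_mask: Optional[np.ndarray] = None,
         trace_rate: Optional[float] = None,
         region_id: Optional[int] = None) -> NVCMaps:
    """Neurovascular correlation maps against one regional neuronal trace.

    For every non-vessel pixel, Pearson correlation between the pixel's
    ΔHbT series and the trace is computed at every integer-frame lag within
    ±``lag_window_s`` (positive lag = ΔHbT delayed re. neurons); the lag
    maximizing |r| defines all three maps. ``trace_rate`` resamples a trace
    acquired at a different rate onto the stack's frame grid (linear
    interpolation).
    """
    trace = np.asarray(regional_trace, dtype=float)
    n = dhbt_stack.n_frames
    fs = dhbt_stack.frame_rate
    if trace_rate is not None and trace_rate != fs:
        trace = _resample_linear(trace, trace_rate, fs, n)
    if trace.size < n:
        raise ValueError("regional trace shorter than the stack")
    trace = trace[:n]
    if np.std(trace) == 0:
        raise ValueError("regional trace has zero variance")
    max_lag = int(round(lag_window_s * fs))
    flat = dhbt_stack.data.reshape(n, -1)
    n_pix = flat.shape[1]
    best_r = np.zeros(n_pix)
    best_cov = np.zeros(n_pix)
    best_lag = np.zeros(n_pix)
    best_abs = np.full(n_pix, -1.0)
    for lag in range(-max_lag, max_lag + 1):
        # positive lag: dhbt(t) vs trace(t − lag)
        if lag >= 0:
            x = trace[: n - lag]
            Y = flat[lag:]
        else:
            x = trace[-lag:]
            Y = flat[: n + lag]
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0, keepdims=True)
        denom_x = np.sqrt((xc * xc).sum())
        denom_y = np.sqrt((Yc * Yc).sum(axis=0))
        cov = xc @ Yc / (x.size - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ Yc) / (denom_x * denom_y)
        take = np.abs(r) > best_abs
        take &= np.isfinite(r)
        best_abs[take] = np.abs(r[take])
        best_r[take] = r[take]
        best_cov[take] = cov[take]
        best_lag[take] = lag / fs
    dead = best_abs < 0
    best_r[dead] = np.nan
    best_cov[dead] = np.nan
    best_lag[dead] = np.nan
    shape = dhbt_stack.frame_shape
    xcorr = best_cov.reshape(shape)
    norm = best_r.reshape(shape)
    lagmap = best_lag.reshape(shape)
    if vessel_mask is not None:
        vm = np.asarray(vessel_mask, bool)
        xcorr[vm] = np.nan
        norm[vm] = np.nan
        lagmap[vm] = np.nan
    return NVCMaps(xcorr, norm, lagmap, lag_window_s, region_id=region_id)


def region_traces(dff_stack: FrameStack,
                  masks: dict[int, np.ndarray]) -> TraceSet:
    """Mask-averaged regional ΔF/F traces (the atlas/seed-mask stand-in for
    factorization-based decomposition of cortex-wide recordings)."""
    stacked = np.stack([np.asarray(m, bool) for m in masks.values()])
    if np.any(stacked.sum(axis=0) > 1):
        raise ValueError("region masks must be disjoint")
    flat = dff_stack.data.reshape(dff_stack.n_frames, -1)
    traces = {}
    for rid, mask in masks.items():
        sel = np.asarray(mask, bool).ravel()
        if not sel.any():
            raise ValueError(f"region {rid} is empty")
        traces[rid] = flat[:, sel].mean(axis=1)
    return TraceSet(traces, dff_stack.frame_rate, "dff")


def timing_histogram(map_values: np.ndarray, bin_width_s: float):
    """Histogram of a timing map's valid pixels (for peak/onset-time
    distributions); returns (bin_edges_s, counts)."""
    vals = map_values[np.isfinite(map_values)]
    if vals.size == 0:
        return np.array([0.0, bin_width_s]), np.array([0])
    lo = np.floor(vals.min() / bin_width_s) * bin_width_s
    hi = np.ceil(vals.max() / bin_width_s) * bin_width_s + bin_width_s
    edges = np.arange(lo, hi + bin_width_s / 2, bin_width_s)
    counts, _ = np.histogram(vals, edges)
    return edges, counts
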