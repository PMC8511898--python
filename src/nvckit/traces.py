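"""Calcium trace processing: ROI extraction, neuropil and hemodynamic
corrections, ΔF/F, denoising, trial averaging and response metrics.

The processing chain mirrors standard practice for somatic GCaMP recordings:

1. average pixels within each hand-drawn ROI;
2. subtract scaled neuropil fluorescence, F_true = F_meas − r·F_neuropil
   (r = 0.7 by default, the empirical contamination ratio);
3. ΔF/F against a 1-s pre-stimulus baseline per trial;
4. optional causal exponentially-weighted moving-average denoising;
5. average across stimulus repetitions (typically 12–24 trials);
6. summarize the averaged response by amplitude, peak time (time of
   maximum) and onset time (baseline intercept of the least-squares line
   through the 20–80 %-of-peak rising limb).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import FrameStack, ResponseMetrics, RoiSet, TraceSet

__all__ = [
    "extract_roi_traces",
    "neuropil_correct",
    "compute_dff",
    "ewma_filter",
    "trial_average",
    "epoch_traces",
    "response_metrics",
]


def extract_roi_traces(stack: FrameStack, roi_set: RoiSet) -> TraceSet:
    """Per-ROI unweighted pixel-mean time series."""
    if roi_set.label_image.shape != stack.frame_shape:
        raise ValueError("ROI label image does not match the frame shape")
    flat = stack.data.reshape(stack.n_frames, -1)
    labels = roi_set.label_image.ravel()
    traces = {}
    for lab in roi_set.labels():
        sel = labels == lab
        if not sel.any():
            raise ValueError(f"ROI {lab} is empty")
        traces[lab] = flat[:, sel].mean(axis=1)
    return TraceSet(traces, stack.frame_rate, "raw", roles=dict(roi_set.roles))


def neuropil_correct(soma_trace: np.ndarray, neuropil_trace: np.ndarray,
                     r: float = 0.7) -> np.ndarray:
    """Neuropil decontamination: F_true(t) = F_measured(t) − r·F_neuropil(t)."""
    if not 0 <= r < 1:
        raise ValueError("contamination ratio r must be in [0, 1)")
    soma_trace = np.asarray(soma_trace, dtype=float)
    neuropil_trace = np.asarray(neuropil_trace, dtype=float)
    if soma_trace.shape != neuropil_trace.shape:
        raise ValueError("soma and neuropil traces must have equal length")
    return soma_trace - r * neuropil_trace


def compute_dff(trace: np.ndarray, sampling_rate: float,
                stimulus_onsets_s: Optional[Sequence[float]] = None,
                baseline_s: float = 1.0,
                baseline_frames: Optional[Sequence[int]] = None,
                roi_id=None) -> np.ndarray:
    """Fractional fluorescence change ΔF(t)/F0.

    Trial mode (``stimulus_onsets_s`` given): F0 for each trial is the mean
    over the ``baseline_s`` window (default 1 s) ending at that trial's
    onset; every sample from one baseline window start to the next is
    normalized by its trial's F0 (samples before the first window use the
    first F0). Continuous mode: F0 from ``baseline_frames``.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    who = f" (roi {roi_id})" if roi_id is not None else ""
    if stimulus_onsets_s is None:
        if baseline_frames is None:
            raise ValueError("need stimulus_onsets_s or baseline_frames")
        f0 = trace[np.asarray(baseline_frames, dtype=int)].mean()
        if f0 <= 0:
            raise ValueError(f"non-positive baseline F0{who}")
        return trace / f0 - 1.0
    nb = max(int(round(baseline_s * sampling_rate)), 1)
    starts = []
    for onset in stimulus_onsets_s:
        i_on = int(round(onset * sampling_rate))
        if i_on - nb < 0:
            raise ValueError(f"onset at {onset} s lacks {baseline_s} s of baseline{who}")
        starts.append(i_on - nb)
    out = np.empty_like(trace)
    bounds = starts + [n]
    for k, s in enumerate(starts):
        f0 = trace[s:s + nb].mean()
        if f0 <= 0:
            raise ValueError(f"non-positive baseline F0 at trial {k}{who}")
        lo = 0 if k == 0 else s
        out[lo:bounds[k + 1]] = trace[lo:bounds[k + 1]] / f0 - 1.0
    return out


def ewma_filter(trace: np.ndarray, time_constant_s: float,
                sampling_rate: float) -> np.ndarray:
    """Causal first-order exponentially-weighted moving average.

    y[t] = λ·y[t−1] + (1−λ)·x[t] with λ = exp(−dt/τ); unit DC gain, so a
    constant input passes unchanged. Initialized at the first sample.
    """
    if time_constant_s <= 0:
        raise ValueError("time_constant_s must be > 0")
    trace = np.asarray(trace, dtype=float)
    lam = float(np.exp(-1.0 / (time_constant_s * sampling_rate)))
    out = np.empty_like(trace)
    acc = trace[0]
    for i, x in enumerate(trace):
        acc = lam * acc + (1.0 - lam) * x
        out[i] = acc
    return out


def epoch_traces(trace: np.ndarray, sampling_rate: float,
                 stimulus_onsets_s: Sequence[float],
                 pre_s: float, post_s: float):
    """Slice a trace into peri-stimulus epochs on a common grid.

    Returns ``(epochs, rel_times_s, n_dropped)``; epochs is
    ``(n_complete_trials, n_samples)``; incomplete trials are dropped.
    """
    trace = np.asarray(trace)
    n = trace.shape[0]
    npre = int(round(pre_s * sampling_rate))
    npost = int(round(post_s * sampling_rate))
    rows, dropped = [], 0
    for onset in stimulus_onsets_s:
        i = int(round(onset * sampling_rate))
        if i - npre < 0 or i + npost > n:
            dropped += 1
            continue
        rows.append(trace[i - npre:i + npost])
    rel_t = (np.arange(npre + npost) - npre) / sampling_rate
    return (np.asarray(rows, dtype=float) if rows else
            np.empty((0, npre + npost))), rel_t, dropped


def trial_average(trace: np.ndarray, sampling_rate: float,
                  stimulus_onsets_s: Sequence[float],
                  pre_s: float = 1.0, post_s: float = 3.0,
                  roi_id: int = 0) -> TraceSet:
    """Time-locked mean ± SEM across stimulus repetitions.

    The returned TraceSet holds the averaged trace under ``roi_id``; its
    ``times`` start at 0 = epoch start (stimulus at ``pre_s``).
    """
    epochs, _, dropped = epoch_traces(trace, sampling_rate,
                                      stimulus_onsets_s, pre_s, post_s)
    if epochs.shape[0] < 2:
        raise ValueError("trial averaging needs at least 2 complete trials")
    if dropped:
        import logging
        logging.getLogger("nvckit").info("trial_average: dropped %d incomplete trials",
                                         dropped)
    mean = epochs.mean(axis=0)
    sem = epochs.std(axis=0, ddof=1) / np.sqrt(epochs.shape[0])
    return TraceSet({roi_id: mean}, sampling_rate, "trial_averaged",
                    trial_sem={roi_id: sem})


def response_metrics(averaged_response: np.ndarray,
                     pre_stimulus_frames: Sequence[int],
                     sampling_rate: float,
                     polarity: int = 1,
                     stimulus_time_s: Optional[float] = None) -> ResponseMetrics:
    """Amplitude, peak time and onset time of an averaged response.

    * baseline — mean over ``pre_stimulus_frames``;
    * peak time — time of maximum (after the pre-stimulus window);
    * amplitude — maximum minus baseline;
    * onset time — where the least-squares line through the rising-limb
      samples between 20 % and 80 % of the amplitude crosses the baseline.
      With fewer than 2 samples in the band, the onset falls back to linear
      interpolation between the samples bracketing the band (flagged).

    ``polarity=-1`` analyses negative-going (OFF) responses by negating the
    trace first. Non-positive amplitude → all-NaN metrics classified
    "non-responsive". The onset is clamped to ``stimulus_time_s`` (if given)
    in the reported value only; fit diagnostics keep the raw intercept.
    """
    y = np.asarray(averaged_response, dtype=float) * polarity
    pre = np.asarray(pre_stimulus_frames, dtype=int)
    if pre.size == 0:
        raise ValueError("pre_stimulus_frames must be non-empty")
    baseline = y[pre].mean()
    search_start = int(pre.max()) + 1
    if search_start >= y.size:
        raise ValueError("no samples after the pre-stimulus window")
    i_peak = search_start + int(np.argmax(y[search_start:]))
    amplitude = y[i_peak] - baseline
    peak_time = i_peak / sampling_rate
    if not amplitude > 0:
        return ResponseMetrics(np.nan, np.nan, np.nan, baseline=baseline * polarity,
                               classification="non-responsive")
    lo_level = baseline + 0.2 * amplitude
    hi_level = baseline + 0.8 * amplitude
    # rising limb: from the last sub-20% sample before the peak to the
    # first supra-80% sample after it
    below = np.nonzero(y[:i_peak + 1] < lo_level)[0]
    i_lo = int(below.max()) if below.size else 0
    above = np.nonzero(y[i_lo:i_peak + 1] > hi_level)[0]
    i_hi = i_lo + int(above.min()) if above.size else i_peak
    band = np.arange(i_lo, i_hi + 1)
    band = band[(y[band] >= lo_level) & (y[band] <= hi_level)]
    fallback = band.size < 2
    if fallback:
        # bracket the band with its neighbours and interpolate the
        # baseline crossing of that chord
        i0, i1 = i_lo, i_hi
        if i1 == i0:
            i0 = max(i0 - 1, 0)
        slope = (y[i1] - y[i0]) * sampling_rate / max(i1 - i0, 1)
        intercept = y[i0] - slope * (i0 / sampling_rate)
    else:
        t = band / sampling_rate
        slope, intercept = np.polyfit(t, y[band], 1)
    onset = (baseline - intercept) / slope if slope != 0 else np.nan
    reported = onset
    if stimulus_time_s is not None and np.isfinite(onset):
        reported = max(onset, stimulus_time_s)
    reported = min(reported, peak_time) if np.isfinite(reported) else reported
    return ResponseMetrics(
        onset_time_s=reported,
        peak_time_s=peak_time,
        amplitude=amplitude,
        baseline=baseline * polarity,
        classification="responsive",
        fit_slope=slope,
        fit_intercept=intercept,
        fit_window=(int(band[0]), int(band[-1])) if band.size else (i_lo, i_hi),
        fallback_interpolated=fallback,
    )
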