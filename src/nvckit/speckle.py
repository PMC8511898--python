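"""Laser speckle contrast flowmetry.

Moving red blood cells blur a coherent-light speckle pattern within the
camera exposure T; the local contrast K = σ/μ therefore falls as flow
increases. Under the Lorentzian (exponential field-correlation) model the
contrast obeys

    K² = β · [ τc/T + τc²/(2T²)·(e^(−2T/τc) − 1) ]

with τc the field correlation time (1/τc proportional to scatterer speed)
and β the speckle coherence factor. For τc ≪ T this reduces to the
asymptotic proxy 1/τc ∝ 1/K², the usual relative-CBF measure.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import brentq

from .datatypes import CbfMap, FrameStack, SpeckleContrastMap

__all__ = [
    "speckle_contrast_model",
    "spatial_contrast",
    "invert_contrast",
    "relative_cbf",
]


def speckle_contrast_model(tauc, exposure_T, beta: float = 1.0):
    """Forward model: K² as a function of τc and exposure T (same units).

    Handles τc → ∞ (static scatterers, K² → β) and τc → 0 (K² → 0).
    """
    tauc = np.asarray(tauc, dtype=float)
    x = tauc / float(exposure_T)
    with np.errstate(over="ignore", invalid="ignore"):
        k2 = np.where(
            np.isinf(x), beta,
            beta * (x + 0.5 * x**2 * np.expm1(-2.0 / np.maximum(x, 1e-300))),
        )
    return k2 if k2.ndim else float(k2)


def spatial_contrast(frames: Union[FrameStack, np.ndarray],
                     window_px: int = 7) -> SpeckleContrastMap:
    """Spatial speckle contrast K = σ/μ in a centered square window
    (default 7×7) around every pixel; borders use reflection padding.

    Sample standard deviation (ddof = 1). Zero-mean windows give NaN.
    """
    if window_px % 2 == 0 or window_px < 3:
        raise ValueError("window_px must be odd and >= 3")
    if isinstance(frames, FrameStack):
        data, exposure = frames.data, frames.exposure_ms
    else:
        data, exposure = np.asarray(frames, dtype=float), None
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]
    if min(data.shape[1:]) < window_px:
        raise ValueError("frame smaller than the contrast window")
    n = window_px * window_px
    size = (1, window_px, window_px)
    m = uniform_filter(data, size, mode="reflect")
    m2 = uniform_filter(data * data, size, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(m != 0, np.sqrt(var) / m, np.nan)
    if squeeze:
        K = K[0]
    return SpeckleContrastMap(K, window_px, exposure_ms=exposure)


def invert_contrast(K, exposure_T: float = 1.0, mode: str = "asymptotic",
                    beta: float = 1.0):
    """Inverse correlation time 1/τc (proportional units) from contrast K.

    mode='asymptotic'
        1/K² — valid for τc ≪ T; units arbitrary (proportional).
    mode='full'
        Solves the full contrast model K² = β·g(τc/T) for τc by bracketed
        root finding (g is strictly increasing, so the root is unique) and
        returns 1/τc in 1/units-of-T. K² ≥ β has no solution → NaN.
    """
    K = np.asarray(K, dtype=float)
    if mode == "asymptotic":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 / (K * K)
        return out if out.ndim else float(out)
    if mode != "full":
        raise ValueError("mode must be 'asymptotic' or 'full'")
    if exposure_T <= 0:
        raise ValueError("exposure_T must be > 0")

    def solve_one(k: float) -> float:
        if not np.isfinite(k) or k <= 0:
            return np.nan
        k2 = k * k
        if k2 >= beta:
            return np.nan  # static limit exceeded: no finite τc
        f = lambda log_x: speckle_contrast_model(np.exp(log_x) * exposure_T,
                                                 exposure_T, beta) - k2
        lo, hi = -30.0, 30.0
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError(f"no bracket for K = {k}")
        log_x = brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)
        return 1.0 / (np.exp(log_x) * exposure_T)

    out = np.vectorize(solve_one, otypes=[float])(K)
    return out if out.ndim else float(out)


def relative_cbf(contrast: Union[SpeckleContrastMap, np.ndarray],
                 baseline_frames) -> CbfMap:
    """CBF proxy 1/K² and its relative change ΔCBF/CBF(t0).

    The baseline proxy image is the average of the pre-stimulus proxy
    frames; rel_change = (proxy(t) − proxy0)/proxy0. K = 0 pixels → NaN.
    """
    K = contrast.K if isinstance(contrast, SpeckleContrastMap) else np.asarray(contrast)
    idx = np.asarray(baseline_frames, dtype=int)
    if idx.size == 0:
        raise ValueError("baseline_frames must be non-empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        proxy = np.where(K > 0, 1.0 / (K * K), np.nan)
        proxy0 = proxy[idx].mean(axis=0)
        rel = (proxy - proxy0[None]) / proxy0[None]
    return CbfMap(proxy, rel_change=rel, baseline_frames=idx)
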