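"""Intrinsic-optical-signal hemodynamics: reflectance to hemoglobin maps.

At an isosbestic wavelength (≈530 nm) oxy- and deoxyhemoglobin absorb
equally, so the modified Beer-Lambert law relates reflectance to total
hemoglobin change:

    ΔHbT(t) = −(1/α) · ln( R(t) / R(t0) ),    α = ½(ε_HbO2 + ε_HbR)·χ

With two wavelengths the per-pixel 2×2 linear system

    −ln(R_λ/R0_λ) = χ(λ) · ( ε_HbO2(λ)·ΔHbO2 + ε_HbR(λ)·ΔHbR )

is solved for the oxy/deoxy split. The same absorption dynamics attenuate
green calcium-indicator fluorescence; the division correction

    (F(t)/F0) / (R(t)/R0)  ≈  F_corr(t)/F_corr(t0)

removes that artifact.

Because the proportionality constant α is rarely known, the default output
is α·ΔHbT (dimensionless, "alpha_scaled"); molar units require a constants
table (:mod:`nvckit.constants`).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .constants import OpticalConstants
from .datatypes import FrameStack, HbMaps

__all__ = [
    "compute_baseline",
    "compute_delta_hbt",
    "unmix_dual_wavelength",
    "hemodynamic_correct",
]

ArrayLike = Union[np.ndarray, Sequence[float]]


def compute_baseline(stack: FrameStack, prestim_frames: ArrayLike,
                     blur_sigma: float = 1.1) -> np.ndarray:
    """Pre-stimulus baseline image: mean over ``prestim_frames`` then
    Gaussian blur (default σ = 1.1 px) to suppress spatial noise.

    ``blur_sigma=0`` skips the blur (plain mean).
    """
    idx = np.asarray(prestim_frames, dtype=int)
    if idx.size == 0:
        raise ValueError("prestim_frames must be non-empty")
    frames = stack.data[idx]
    if np.any(frames <= 0):
        raise ValueError("baseline frames must be strictly positive")
    base = frames.mean(axis=0)
    if blur_sigma > 0:
        base = gaussian_filter(base, blur_sigma, mode="reflect")
    if np.any(base <= 0):
        raise ValueError("blurred baseline contains non-positive pixels")
    return base


def compute_delta_hbt(stack: FrameStack, baseline: np.ndarray,
                      alpha: Optional[float] = None,
                      baseline_frames: Optional[np.ndarray] = None) -> HbMaps:
    """Total-hemoglobin change per pixel from single-wavelength reflectance.

    Returns α·ΔHbT (dimensionless) when ``alpha`` is None, else ΔHbT = value/α
    in the units implied by α. Transiently non-positive pixels (noise) are
    masked NaN and propagate downstream.
    """
    if alpha is not None and alpha <= 0:
        raise ValueError("alpha must be > 0")
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive")
    data = np.asarray(stack.data, dtype=float)
    bad = data <= 0
    if bad.any():
        frames = np.unique(np.nonzero(bad)[0])
        if bad.all(axis=(1, 2)).any():
            raise ValueError(f"non-positive reflectance throughout frame(s) {frames.tolist()}")
        data = np.where(bad, np.nan, data)
    ratio = data / baseline[None]
    dhbt = -np.log(ratio)
    if alpha is not None:
        dhbt = dhbt / alpha
    return HbMaps(dhbt, "alpha_scaled" if alpha is None else "molar",
                  baseline_frames=baseline_frames, frame_rate=stack.frame_rate)


def _pair_frames(stack_a: FrameStack, stack_b: FrameStack):
    """Pair frames of two (possibly interleaved) channels by nearest
    timestamp, with maximum skew of half the slower inter-frame interval."""
    ta, tb = stack_a.times, stack_b.times
    if ta.size == tb.size and np.allclose(ta, tb):
        return np.arange(ta.size), np.arange(ta.size)
    tol = 0.5 / min(stack_a.frame_rate, stack_b.frame_rate)
    jb = np.searchsorted(tb, ta)
    jb = np.clip(jb, 0, tb.size - 1)
    jb_prev = np.clip(jb - 1, 0, tb.size - 1)
    use_prev = np.abs(tb[jb_prev] - ta) < np.abs(tb[jb] - ta)
    jb = np.where(use_prev, jb_prev, jb)
    ok = np.abs(tb[jb] - ta) <= tol
    if not ok.any():
        raise ValueError("channels cannot be paired: frame counts/timing mismatch")
    return np.nonzero(ok)[0], jb[ok]


def unmix_dual_wavelength(stack_a: FrameStack, stack_b: FrameStack,
                          constants: OpticalConstants,
                          wavelengths_nm: tuple[float, float],
                          prestim_frames: ArrayLike,
                          blur_sigma: float = 1.1,
                          max_condition: float = 1e6) -> HbMaps:
    """Solve the per-pixel 2×2 Beer-Lambert system for (ΔHbO2, ΔHbR) in µM.

    Frames of the two channels are paired by nearest timestamp (interleaved
    acquisition); each channel gets its own blurred pre-stimulus baseline.
    """
    wl_a, wl_b = wavelengths_nm
    for wl in (wl_a, wl_b):
        if wl not in constants:
            raise ValueError(f"constants table lacks wavelength {wl} nm")
    A = constants.unmix_matrix(wl_a, wl_b)
    cond = np.linalg.cond(A)
    if cond > max_condition:
        raise ValueError(f"unmixing system ill-conditioned (cond = {cond:.3g})")
    ia, ib = _pair_frames(stack_a, stack_b)
    base_a = compute_baseline(stack_a, prestim_frames, blur_sigma)
    base_b = compute_baseline(stack_b, prestim_frames, blur_sigma)
    od_a = -np.log(stack_a.data[ia] / base_a[None])  # optical density changes
    od_b = -np.log(stack_b.data[ib] / base_b[None])
    rhs = np.stack([od_a, od_b], axis=-1)  # (t, y, x, 2)
    sol = np.linalg.solve(A[None, None, None], rhs[..., None])[..., 0]  # molar
    dhbo2 = sol[..., 0] * 1e6  # µM
    dhbr = sol[..., 1] * 1e6
    return HbMaps(dhbo2 + dhbr, "molar", dHbO2=dhbo2, dHbR=dhbr,
                  baseline_frames=np.asarray(prestim_frames, dtype=int),
                  frame_rate=stack_a.frame_rate)


def hemodynamic_correct(fluor_ratio: np.ndarray,
                        reflect_ratio: np.ndarray) -> np.ndarray:
    """Division-based hemodynamic correction for 1P calcium imaging.

    Both inputs are ratios to their own pre-stimulus baselines
    (F(t)/F(t0) and R(t)/R(t0)); shapes broadcast (pixelwise or per-ROI).
    Returns the corrected fractional change ΔF_corr/F_corr = F/F0 ÷ R/R0 − 1.
    """
    fluor_ratio = np.asarray(fluor_ratio, dtype=float)
    reflect_ratio = np.asarray(reflect_ratio, dtype=float)
    if np.any(reflect_ratio <= 0):
        raise ValueError("reflectance ratio must be strictly positive")
    return fluor_ratio / reflect_ratio - 1.0
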