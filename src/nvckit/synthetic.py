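"""Synthetic acquisition models with known ground truth.

Every generator returns ``(data, GroundTruth)``; identical seeds give
bit-identical output (all randomness flows through one
``numpy.random.default_rng(seed)``). Each forward model is the exact
inverse of the corresponding analysis stage, so at zero noise the pipeline
recovers the truth to floating-point precision — the core verification
contract of the package.

Forward models
--------------
speckle
    Per-pixel complex Gaussian field with exponential temporal
    autocorrelation exp(−t/τc) (Ornstein-Uhlenbeck update), intensity
    integrated over the camera exposure with sub-exposure sampling at
    ≤ τc/4 — the model under which the Lorentzian contrast formula
    K² = β[τc/T + τc²/2T²(e^(−2T/τc)−1)] is exact.
reflectance
    Beer-Lambert attenuation R(t) = R0·exp(−α·ΔHbT(t)); dual-wavelength
    variant uses per-wavelength extinction coefficients and path lengths.
calcium session
    Somata with difference-of-exponentials transients, neuropil
    contamination F_meas = F_true + r·F_np, and multiplicative hemodynamic
    attenuation of the whole fluorescence frame, paired with the matching
    reflectance stack.
vessel movie
    Anti-aliased bright disk (plasma-labeled lumen) of known per-frame
    diameter, optional Gaussian PSF blur and additive noise.
line scan
    Bright plasma background with dark Gaussian-profile RBC streaks whose
    slope (px/line) is exactly v·Δt/Δx.
NVC session
    dHbT(pixel, t) = gain·(neural trace ⊛ gamma HRF)(t − lag) + noise,
    paired with the dF/F movie; vessel-mask pixels carry independent
    dynamics.
tonal session
    One response per sweep period at a per-pixel phase, for Fourier
    tonotopy.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .constants import OpticalConstants
from .datatypes import FrameStack, GroundTruth, LineScan, RoiSet

__all__ = [
    "gen_speckle_stack",
    "gen_reflectance_stack",
    "gen_dual_reflectance_stacks",
    "gen_calcium_session",
    "gen_vessel_movie",
    "gen_linescan",
    "gen_nvc_session",
    "gen_tonal_session",
    "calcium_kernel",
    "gamma_hrf",
]


# ---------------------------------------------------------------- speckle

def gen_speckle_stack(shape: tuple[int, int], tauc_map_ms, exposure_T_ms: float,
                      n_frames: int, seed: int, beta: float = 1.0,
                      mean_intensity: float = 1.0, frame_rate: float = 30.0,
                      sub_dt_ms: Optional[float] = None,
                      max_substeps: int = 50000):
    """Exposure-integrated dynamic speckle with per-pixel correlation time.

    ``tauc_map_ms`` may contain ``inf`` (static scatterers). ``beta`` is the
    coherence factor: 1 = fully developed speckle; values in (0, 1) add an
    incoherent constant background; 0 bypasses speckle entirely (uniform
    intensity, K = 0).
    """
    if exposure_T_ms <= 0:
        raise ValueError("exposure_T_ms must be > 0")
    tauc = np.broadcast_to(np.asarray(tauc_map_ms, dtype=float), shape).copy()
    if np.any(tauc <= 0):
        raise ValueError("tauc_map must be > 0 everywhere")
    truth = GroundTruth("speckle", {
        "tauc_map_ms": tauc, "exposure_T_ms": exposure_T_ms, "beta": beta,
        "mean_intensity": mean_intensity,
    }, seed)
    if beta == 0.0:
        data = np.full((n_frames, *shape), mean_intensity)
        return FrameStack(data, frame_rate, "speckle_635",
                          exposure_ms=min(exposure_T_ms, 1000 / frame_rate)), truth
    rng = np.random.default_rng(seed)
    finite = tauc[np.isfinite(tauc)]
    if sub_dt_ms is None:
        sub_dt_ms = (finite.min() / 4.0) if finite.size else exposure_T_ms
    nsub = max(int(np.ceil(exposure_T_ms / sub_dt_ms)), 1)
    if nsub > max_substeps:
        raise ValueError(
            f"exposure/τc ratio needs {nsub} sub-exposure samples "
            f"(> budget {max_substeps}); raise max_substeps or sub_dt_ms")
    dt = exposure_T_ms / nsub
    with np.errstate(divide="ignore"):
        rho = np.exp(-dt / tauc)  # exp(-dt/inf) = 1
    c = np.sqrt(1.0 - rho**2)

    def fresh():
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)

    E = fresh()
    frames = np.empty((n_frames, *shape))
    for f in range(n_frames):
        acc = np.zeros(shape)
        for _ in range(nsub):
            E = rho * E + c * fresh()
            acc += E.real**2 + E.imag**2
        frames[f] = acc / nsub
    if beta < 1.0:
        # incoherent background dilutes contrast: K -> sqrt(beta)*K
        background = 1.0 / np.sqrt(beta) - 1.0
        frames = frames + background
        frames *= mean_intensity / (1.0 + background)
    else:
        frames *= mean_intensity
    return FrameStack(frames, frame_rate, "speckle_635",
                      exposure_ms=min(exposure_T_ms, 1000 / frame_rate)), truth


# ----------------------------------------------------------- reflectance

def gen_reflectance_stack(baseline_image: np.ndarray, hbt_timecourse,
                          alpha: float = 1.0, noise_sd: float = 0.0,
                          seed: int = 0, frame_rate: float = 30.0,
                          channel: str = "reflect_530"):
    """Single-wavelength Beer-Lambert reflectance: R(t) = R0·exp(−α·ΔHbT(t)).

    ``hbt_timecourse`` is ΔHbT per frame, shape ``(t,)`` or ``(t, y, x)``
    (broadcast against the baseline image).
    """
    baseline_image = np.asarray(baseline_image, dtype=float)
    if np.any(baseline_image <= 0):
        raise ValueError("baseline_image must be strictly positive")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    hbt = np.asarray(hbt_timecourse, dtype=float)
    if hbt.ndim == 1:
        hbt = hbt[:, None, None]
    clean = baseline_image[None] * np.exp(-alpha * hbt)
    if np.any(clean <= 0):
        raise ValueError("requested reflectance is non-positive (unphysical)")
    rng = np.random.default_rng(seed)
    data = clean + (rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 0.0)
    truth = GroundTruth("reflectance", {
        "alpha": alpha, "hbt_timecourse": np.broadcast_to(
            hbt, clean.shape).copy(), "baseline_image": baseline_image,
        "noise_sd": noise_sd,
    }, seed)
    return FrameStack(data, frame_rate, channel), truth


def gen_dual_reflectance_stacks(baseline_images: tuple[np.ndarray, np.ndarray],
                                dhbo2_uM, dhbr_uM,
                                constants: OpticalConstants,
                                wavelengths_nm: tuple[float, float] = (530.0, 460.0),
                                noise_sd: float = 0.0, seed: int = 0,
                                frame_rate: float = 30.0):
    """Two-wavelength reflectance from known (ΔHbO2, ΔHbR) fields in µM.

    Each channel applies its own extinction coefficients and path length:
    −ln(R_λ/R0_λ) = χ(λ)(ε_HbO2(λ)ΔHbO2 + ε_HbR(λ)ΔHbR).
    """
    dhbo2 = np.asarray(dhbo2_uM, dtype=float) * 1e-6  # to molar
    dhbr = np.asarray(dhbr_uM, dtype=float) * 1e-6
    channels = {530.0: "reflect_530", 460.0: "reflect_460"}
    stacks = []
    rng = np.random.default_rng(seed)
    for wl, base in zip(wavelengths_nm, baseline_images):
        base = np.asarray(base, dtype=float)
        if np.any(base <= 0):
            raise ValueError("baseline images must be strictly positive")
        c = constants[wl]
        od = c.path_length_cm * (c.epsilon_hbo2 * dhbo2 + c.epsilon_hbr * dhbr)
        if od.ndim == 1:
            od = od[:, None, None]
        clean = base[None] * np.exp(-od)
        data = clean + (rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 0.0)
        stacks.append(FrameStack(data, frame_rate, channels.get(wl, "reflect_530")))
    truth = GroundTruth("reflectance", {
        "dhbo2_uM": np.asarray(dhbo2_uM, dtype=float),
        "dhbr_uM": np.asarray(dhbr_uM, dtype=float),
        "wavelengths_nm": wavelengths_nm, "noise_sd": noise_sd,
    }, seed)
    return tuple(stacks), truth


# ---------------------------------------------------------------- calcium

def calcium_kernel(sampling_rate: float, rise_s: float = 0.2,
                   decay_s: float = 1.5, support_s: Optional[float] = None) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to 1.

    ``support_s`` hard-truncates the kernel (used by the session generator
    to keep trials exactly separable); None keeps ~8 decay constants.
    """
    if support_s is None:
        support_s = 8.0 * decay_s
    t = np.arange(0.0, support_s, 1.0 / sampling_rate)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise >= decay?)")
    return k / peak


def _disk_mask(shape, cy, cx, radius):
    y, x = np.mgrid[0:shape[0], 0:shape[1]]
    return (y - cy) ** 2 + (x - cx) ** 2 <= radius**2


def gen_calcium_session(shape: tuple[int, int] = (48, 48),
                        n_somata: int = 4,
                        event_times_s: Optional[Sequence[float]] = None,
                        event_amplitude: float = 0.5,
                        rise_s: float = 0.2, decay_s: float = 1.5,
                        neuropil_r: float = 0.7,
                        neuropil_amplitude: float = 0.2,
                        hemo_attenuation_depth: float = 0.1,
                        noise_sd: float = 0.0, seed: int = 0,
                        frame_rate: float = 10.0,
                        inter_stimulus_interval_s: float = 10.0,
                        n_trials: int = 4, baseline_s: float = 1.0):
    """Stimulus-locked calcium session with known contaminations.

    Builds a fluorescence movie (somata + surrounding neuropil annuli), the
    paired reflectance movie encoding the hemodynamic attenuation, and the
    ROI layout. Soma pixels carry ``(F_true + r·F_np)·a(t)``, neuropil
    pixels ``F_np·a(t)``, and reflectance ``R0·a(t)``, so neuropil
    subtraction (with the same r) followed by the ratio-division hemodynamic
    correction recovers the true ΔF/F exactly at zero noise.

    Transients use a difference-of-exponentials kernel truncated at the
    inter-stimulus interval minus the baseline window, which keeps each
    trial's pre-stimulus baseline free of earlier-trial tails (trials are
    exactly separable; the truncated tail is < 0.3 % of peak at defaults).
    """
    if not 0 <= neuropil_r < 1:
        raise ValueError("neuropil_r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if event_times_s is None:
        event_times_s = [baseline_s + 0.5 + k * inter_stimulus_interval_s
                         for k in range(n_trials)]
    onsets = np.asarray(event_times_s, dtype=float)
    duration_s = onsets.max() + inter_stimulus_interval_s
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate

    support = inter_stimulus_interval_s - baseline_s - 2.0 / frame_rate
    kernel = calcium_kernel(frame_rate, rise_s, decay_s, support_s=support)
    dff_events = np.zeros(n_frames)
    for onset in onsets:
        i = int(round(onset * frame_rate))
        seg = kernel[: n_frames - i]
        dff_events[i:i + seg.size] += event_amplitude * seg

    # ROI layout: somata on a grid, each with a neuropil annulus
    ny, nx = shape
    label = np.zeros(shape, dtype=np.int32)
    roles: dict[int, str] = {}
    grid = int(np.ceil(np.sqrt(n_somata)))
    pitch_y, pitch_x = ny // grid, nx // grid
    soma_r, np_r = 3, 7
    soma_ids, np_ids = [], []
    for s in range(n_somata):
        cy = (s // grid) * pitch_y + pitch_y // 2
        cx = (s % grid) * pitch_x + pitch_x // 2
        soma = _disk_mask(shape, cy, cx, soma_r)
        annulus = _disk_mask(shape, cy, cx, np_r) & ~soma
        sid, nid = 2 * s + 1, 2 * s + 2
        if np.any(label[soma | annulus] != 0):
            raise ValueError("overlapping ROI masks in layout")
        label[soma] = sid
        label[annulus] = nid
        roles[sid] = "soma"
        roles[nid] = "neuropil"
        soma_ids.append(sid)
        np_ids.append(nid)
    roi = RoiSet(label, roles)

    # hemodynamic attenuation: stimulus-locked dip, same truncated support
    hrf = gamma_hrf(frame_rate, peak_s=1.5, support_s=support)
    atten = np.ones(n_frames)
    for onset in onsets:
        i = int(round(onset * frame_rate))
        seg = hrf[: n_frames - i]
        atten[i:i + seg.size] -= hemo_attenuation_depth * seg
    if np.any(atten <= 0):
        raise ValueError("attenuation depth too large (non-positive transmission)")

    f0_soma, f0_np, r0 = 100.0, 60.0, 1000.0
    dff_np = neuropil_amplitude / max(event_amplitude, 1e-12) * dff_events
    f_np = f0_np * (1.0 + dff_np)
    movie = np.empty((n_frames, ny, nx))
    background = f0_np * 0.5
    movie[:] = background
    true_dff = {}
    for sid, nid in zip(soma_ids, np_ids):
        f_true = f0_soma * (1.0 + dff_events)
        movie[:, label == sid] = (f_true + neuropil_r * f_np)[:, None]
        movie[:, label == nid] = f_np[:, None]
        true_dff[sid] = dff_events.copy()
    movie *= atten[:, None, None]
    if noise_sd > 0:
        movie = np.clip(movie + rng.normal(0, noise_sd, movie.shape), 0, None)
    reflect = r0 * atten[:, None, None] * np.ones(shape)[None]

    truth = GroundTruth("calcium", {
        "true_dff": true_dff, "event_times_s": onsets,
        "event_amplitude": event_amplitude, "neuropil_r": neuropil_r,
        "attenuation": atten, "baseline_s": baseline_s,
        "soma_ids": soma_ids, "neuropil_ids": np_ids,
        "frame_rate": frame_rate, "noise_sd": noise_sd,
    }, seed)
    fluor = FrameStack(movie, frame_rate, "fluor_470")
    reflect_stack = FrameStack(reflect, frame_rate, "reflect_530")
    return fluor, reflect_stack, roi, truth


# ----------------------------------------------------------------- vessel

def gen_vessel_movie(diameter_trace_um, pixel_size_um: float = 1.0,
                     psf_sigma_px: float = 0.0, noise_sd: float = 0.0,
                     seed: int = 0, frame_rate: float = 30.0,
                     shape: Optional[tuple[int, int]] = None):
    """Movie of a bright filled-disk lumen with known per-frame diameter.

    The disk edge is anti-aliased (linear coverage ramp over one pixel), so
    the rasterized area tracks π(D/2)² to sub-pixel accuracy.
    """
    d_um = np.atleast_1d(np.asarray(diameter_trace_um, dtype=float))
    d_px = d_um / pixel_size_um
    if np.any(d_px < 3):
        raise ValueError("diameter below the 3-pixel resolvable contract")
    margin = 4.0 * psf_sigma_px
    # generous default margin: area analysis assumes the lumen fills well
    # under half of the analysed region
    need = int(np.ceil(1.8 * (d_px.max() + 2 * margin))) + 8
    if shape is None:
        shape = (need, need)
    if min(shape) < d_px.max() + 2 * margin:
        raise ValueError("max diameter + 4·psf_sigma does not fit in the frame")
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y, x = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(y - cy, x - cx)
    rng = np.random.default_rng(seed)
    frames = np.empty((d_px.size, ny, nx))
    for i, d in enumerate(d_px):
        lumen = np.clip(d / 2.0 + 0.5 - dist, 0.0, 1.0)
        if psf_sigma_px > 0:
            lumen = gaussian_filter(lumen, psf_sigma_px)
        frames[i] = lumen
    if noise_sd > 0:
        frames = frames + rng.normal(0, noise_sd, frames.shape)
    truth = GroundTruth("vessel", {
        "diameter_um": d_um, "diameter_px": d_px,
        "pixel_size_um": pixel_size_um, "psf_sigma_px": psf_sigma_px,
        "noise_sd": noise_sd,
    }, seed)
    return FrameStack(np.clip(frames, 0, None) if noise_sd == 0 else frames,
                      frame_rate, "twophoton_red"), truth


# --------------------------------------------------------------- linescan

def gen_linescan(velocity_mm_s: float, dx_um_per_px: float = 1.0,
                 dt_ms_per_line: float = 1.0, rbc_linear_density: float = 0.1,
                 streak_width_px: float = 2.0, n_lines: int = 1000,
                 n_px: int = 128, streak_depth: float = 0.6,
                 noise_sd: float = 0.0, seed: int = 0):
    """Capillary line scan: dark RBC streaks on a bright plasma background.

    Streak slope in pixel units is exactly ``velocity·dt/dx`` px/line
    (mm/s ≡ µm/ms); positive velocity tilts streaks toward increasing
    position with increasing line index.
    """
    slope = velocity_mm_s * dt_ms_per_line / dx_um_per_px  # px per line
    if abs(slope) > n_px / 2.0:
        raise ValueError("velocity too high: streak advances more than half "
                         "the spatial extent per line")
    rng = np.random.default_rng(seed)
    # streak intercepts cover every line of the window
    if slope >= 0:
        b_lo, b_hi = -slope * n_lines - 4 * streak_width_px, n_px + 4 * streak_width_px
    else:
        b_lo, b_hi = -4 * streak_width_px, n_px - slope * n_lines + 4 * streak_width_px
    n_streaks = rng.poisson(rbc_linear_density * (b_hi - b_lo))
    intercepts = np.sort(rng.uniform(b_lo, b_hi, n_streaks))
    lines = np.arange(n_lines)
    xgrid = np.arange(n_px)
    img = np.ones((n_lines, n_px))
    for b in intercepts:
        centers = b + slope * lines
        visible = (centers > -4 * streak_width_px) & (centers < n_px + 4 * streak_width_px)
        if not visible.any():
            continue
        sel = np.nonzero(visible)[0]
        prof = np.exp(-0.5 * ((xgrid[None] - centers[sel, None]) / streak_width_px) ** 2)
        img[sel] -= streak_depth * prof
    img = np.clip(img, 0.0, None)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    warnings = []
    duty = rbc_linear_density * 2.0 * streak_width_px
    if duty > 0.9:
        warnings.append(f"streak duty cycle {duty:.2f} > 0.9: streaks merge")
    angle = float(np.degrees(np.arctan(slope)))
    truth = GroundTruth("linescan", {
        "velocity_mm_s": velocity_mm_s, "slope_px_per_line": slope,
        "angle_deg_from_time_axis": angle, "n_streaks": int(n_streaks),
        "dx_um_per_px": dx_um_per_px, "dt_ms_per_line": dt_ms_per_line,
        "noise_sd": noise_sd,
    }, seed, warnings=warnings)
    return LineScan(img, dx_um_per_px, dt_ms_per_line), truth


# ------------------------------------------------------------ NVC session

def gamma_hrf(sampling_rate: float, peak_s: float = 1.5, shape_k: float = 3.0,
              support_s: Optional[float] = None) -> np.ndarray:
    """Gamma-variate hemodynamic response function, peak-normalized to 1.

    Peak occurs at ``(k−1)·θ``; θ is derived from ``peak_s``.
    """
    theta = peak_s / (shape_k - 1.0)
    if support_s is None:
        support_s = peak_s + 8.0 * theta
    t = np.arange(0.0, support_s, 1.0 / sampling_rate)
    h = t ** (shape_k - 1.0) * np.exp(-t / theta)
    return h / h.max()


def gen_nvc_session(shape: tuple[int, int] = (32, 32),
                    region_masks: Optional[dict[int, np.ndarray]] = None,
                    neural_traces: Optional[dict[int, np.ndarray]] = None,
                    lag_s: float = 1.5, hrf_peak_s: float = 1.5,
                    gain: float = 1.0, vessel_mask: Optional[np.ndarray] = None,
                    noise_sd: float = 0.0, seed: int = 0,
                    frame_rate: float = 10.0, n_frames: int = 1000):
    """Paired (dF/F, dHbT) movies with known hemodynamic lag per region.

    dHbT(pixel, t) = gain·(region trace ⊛ gamma HRF)(t − lag) + noise for
    parenchymal pixels of each region; vessel-mask pixels get independent
    smoothed-noise dynamics. The gamma HRF is applied as a zero-phase
    (forward-backward) filter: a causal skewed kernel would drag the
    cross-correlation peak beyond the stated lag, whereas the zero-phase
    application guarantees ``lag_s`` *is* the lag at which the hemodynamic
    signal correlates maximally with the neural trace. The lag is realized
    as an integer number of frames (recorded in the truth).
    """
    if lag_s < 0:
        raise ValueError("lag_s must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    if region_masks is None:
        half = nx // 2
        m1 = np.zeros(shape, bool)
        m1[:, :half] = True
        m2 = np.zeros(shape, bool)
        m2[:, half:] = True
        region_masks = {1: m1, 2: m2}
    if vessel_mask is not None:
        vessel_mask = np.asarray(vessel_mask, bool)
        for rid, m in region_masks.items():
            if np.any(m & vessel_mask):
                raise ValueError(f"region {rid} overlaps the vessel mask")
    if neural_traces is None:
        neural_traces = {}
        for rid in region_masks:
            raw = rng.normal(0, 1, n_frames)
            neural_traces[rid] = gaussian_filter(raw, 3.0, mode="nearest")
    hrf = gamma_hrf(frame_rate, hrf_peak_s)
    hrf = hrf / hrf.sum()
    lag_frames = int(round(lag_s * frame_rate))
    dff = np.zeros((n_frames, ny, nx))
    dhbt = np.zeros((n_frames, ny, nx))
    for rid, mask in region_masks.items():
        trace = np.asarray(neural_traces[rid], dtype=float)
        # zero-phase: convolve forward then backward; effective kernel is
        # the (symmetric) autocorrelation of the HRF, centered at zero
        full = np.convolve(np.convolve(trace, hrf), hrf[::-1])
        hemo = full[hrf.size - 1:hrf.size - 1 + n_frames]
        hemo = np.roll(hemo, lag_frames)
        hemo[:lag_frames] = 0.0
        dff[:, mask] = trace[:, None]
        dhbt[:, mask] = gain * hemo[:, None]
    if vessel_mask is not None and vessel_mask.any():
        n_v = int(vessel_mask.sum())
        indep = gaussian_filter(rng.normal(0, 1, (n_frames, n_v)), (5.0, 0),
                                mode="nearest")
        dhbt[:, vessel_mask] = indep
    if noise_sd > 0:
        dff = dff + rng.normal(0, noise_sd, dff.shape)
        dhbt = dhbt + rng.normal(0, noise_sd, dhbt.shape)
    truth = GroundTruth("session", {
        "lag_s": lag_frames / frame_rate, "lag_frames": lag_frames,
        "gain": gain, "neural_traces": neural_traces,
        "region_masks": region_masks, "hrf_peak_s": hrf_peak_s,
        "noise_sd": noise_sd, "frame_rate": frame_rate,
    }, seed)
    return (FrameStack(dff, frame_rate, "fluor_470"),
            FrameStack(dhbt, frame_rate, "reflect_530"), truth)


# ---------------------------------------------------------- tonal session

def gen_tonal_session(phase_map_rad: np.ndarray, sweep_period_s: float = 15.0,
                      n_sweeps: int = 4, frame_rate: float = 10.0,
                      response_kernel: Optional[np.ndarray] = None,
                      amplitude_map: Optional[np.ndarray] = None,
                      noise_sd: float = 0.0, seed: int = 0):
    """Periodic-sweep session: each pixel responds once per sweep at a time
    set by its phase (phase 2π = one sweep period).

    The per-pixel response time is quantized to the frame grid; the realized
    phase map and the kernel's own phase at the sweep frequency are recorded
    in the truth. The sweep period must be an integer number of frames.
    """
    if n_sweeps < 2:
        raise ValueError("n_sweeps must be >= 2")
    period_frames_f = sweep_period_s * frame_rate
    period_frames = int(round(period_frames_f))
    if abs(period_frames_f - period_frames) > 1e-9:
        raise ValueError("sweep_period must be an integer number of frames")
    phase = np.asarray(phase_map_rad, dtype=float)
    shape = phase.shape
    if response_kernel is None:
        response_kernel = np.array([1.0])  # delta response
    kernel = np.asarray(response_kernel, dtype=float)
    n_frames = n_sweeps * period_frames
    rng = np.random.default_rng(seed)
    amp = np.ones(shape) if amplitude_map is None else np.asarray(amplitude_map, float)

    offsets = np.mod(np.round(np.mod(phase, 2 * np.pi) / (2 * np.pi)
                              * period_frames).astype(int), period_frames)
    realized_phase = 2 * np.pi * offsets / period_frames
    # base periodic response for offset 0, then roll per distinct offset
    base = np.zeros(n_frames)
    for k in range(n_sweeps):
        seg = kernel[: n_frames - k * period_frames]
        base[k * period_frames:k * period_frames + seg.size] += seg
    data = np.zeros((n_frames, *shape))
    for off in np.unique(offsets):
        sel = offsets == off
        data[:, sel] = np.roll(base, off)[:, None]
    data *= amp[None]
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, data.shape)
    freqs = np.exp(-2j * np.pi * np.arange(kernel.size) / period_frames)
    kernel_phase = float(np.angle(np.sum(kernel * freqs)))
    truth = GroundTruth("tonal", {
        "phase_map_rad": phase, "realized_phase_rad": realized_phase,
        "offset_frames": offsets, "sweep_period_s": sweep_period_s,
        "kernel_phase_rad": kernel_phase, "frame_rate": frame_rate,
        "noise_sd": noise_sd,
    }, seed)
    return FrameStack(data, frame_rate, "fluor_470"), truth
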