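# Methods

This note documents the models behind each analysis stage, the forward
models the synthetic generators implement, the numerical choices that were
genuinely open, and what the passing test suite does and does not establish
about real data.

## Conventions

Movies are `(t, y, x)` float arrays with 0-based pixel centers; line scans
are `(line, position)`. Masks are per-pixel binary membership. All
randomness flows through `numpy.random.default_rng(seed)`, so identical
seeds give bit-identical data. Transiently unphysical pixels (non-positive
reflectance, zero-variance windows) become NaN and propagate; they are
never silently clipped.

## Hemoglobin imaging (modified Beer-Lambert)

At an isosbestic wavelength (≈530 nm) oxy- and deoxyhemoglobin absorb
equally, so diffuse reflectance tracks total hemoglobin:
ΔHbT = −(1/α)·ln(R(t)/R(t₀)) with α = ½(ε_HbO₂+ε_HbR)·χ. The proportionality
constant α depends on the mean photon path length χ, which is
preparation-specific and rarely known; the default output is therefore
**α·ΔHbT, dimensionless**, and molar units are produced only when the user
supplies a constants table. The shipped defaults (`nvckit.constants`) are
Prahl-compilation-style extinction coefficients at 530/460 nm with
literature-order Monte-Carlo path lengths; every round-trip in the test
suite is invariant to their exact values because generator and unmixer
share the table.

The baseline image is the pre-stimulus mean blurred with a σ = 1.1 px
Gaussian (spatial-noise suppression); `blur_sigma=0` disables it. Dual
wavelength unmixing solves the per-pixel 2×2 system by a single
`linalg.solve` after pairing interleaved frames by nearest timestamp
(maximum skew: half the slower frame interval); the system's condition
number is checked against 1e6.

The division-based hemodynamic correction for green fluorescence,
(F/F₀)/(R/R₀) − 1, assumes absorption acts multiplicatively and identically
on excitation+emission as on reflectance. The calcium-session generator
applies contamination in exactly the order the corrections invert
(neuropil addition, then multiplicative attenuation of the whole
fluorescence frame, with the reflectance frame carrying the same
attenuation), so at zero noise the chain is exact to float precision.

## Laser speckle contrast

Spatial contrast K = σ/μ is computed in a centered 7×7 window (sample SD,
ddof = 1) with reflect padding; temporal contrast is deliberately not
implemented. Under the Lorentzian (exponential field-correlation) model,

K² = β[ τc/T + τc²/2T² (e^(−2T/τc) − 1) ],

which is monotone in τc, so `mode="full"` inversion uses bracketed Brent
root finding on log τc (unique root; K² ≥ β → NaN, no finite solution).
`mode="asymptotic"` returns 1/K², the usual relative-flow proxy, valid for
τc ≪ T; the two agree to < 2 % for τc/T ≤ 0.01. β (speckle coherence
factor) defaults to 1 and is a free generator/analysis parameter, as is the
exposure T.

The speckle generator integrates a per-pixel complex Gaussian
Ornstein-Uhlenbeck field (autocorrelation e^(−t/τc)) over the exposure with
sub-exposure steps ≤ τc/4 — the exact model under which the contrast
formula is derived, so measured contrast converges to the formula without
fitted constants. β < 1 is realized by adding an incoherent constant
background; β = 0 bypasses speckle (uniform frames, K = 0). A sub-step
budget guards against pathological T/τc ratios.

## Calcium traces

The chain is raw → neuropil-corrected → ΔF/F → filtered → trial-averaged,
enforced on `TraceSet.kind`. Neuropil correction subtracts r = 0.7 of the
surrounding-annulus trace (the value standard for moderate-NA widefield
objectives); the generator's annulus has a 7-px radius around a 3-px soma.
ΔF/F normalizes each trial by the mean over the 1 s before its stimulus
onset. The EWMA denoiser is the causal recursion y[t] = λy[t−1] + (1−λ)x[t],
λ = e^(−dt/τ), default τ = 0.2 s — mild smoothing well below the indicator
decay time; a bidirectional variant was considered and rejected to keep
onset latencies causal.

Response metrics on a trial-averaged trace: baseline = pre-stimulus mean;
peak time = time of the maximum after the baseline window (ties → earliest);
amplitude = max − baseline; onset = baseline intercept of the least-squares
line through the rising-limb samples between 20 % and 80 % of amplitude
(from the last sub-20 % sample before the peak to the first supra-80 %
sample). With fewer than two in-band samples the onset falls back to the
chord between the bracketing samples and is flagged. Negative-going (OFF)
responses are handled by a polarity flag that negates the trace first.
Onset is clamped to the stimulus time (and to the peak time) only in the
reported value, never in the fit.

The generator's transient kernel is a difference of exponentials
(rise 0.2 s, decay 1.5 s, peak-normalized — GCaMP6s-like), hard-truncated
at the inter-stimulus interval minus the baseline window. The truncation
(< 0.3 % of peak at defaults) makes trials exactly separable, so event
amplitudes are recovered to float precision rather than to a
tail-contamination floor; it is a fixture property, not a claim about real
indicator kinetics.

## Vessel diameter

**Radon-space area.** The ROI-cropped, background-subtracted frame
(background = median, unbiased under symmetric noise while the lumen fills
< 50 % of the region — ROIs must carry margin) is upsampled ×2 bilinearly,
Radon transformed over 0–179° in 1° steps, each projection binarized at
half its maximum, and the binary sinogram back-projected **without
filtering**; the area is the count of pixels above 2/3 of the
back-projection maximum. The 2/3 level is not a tuning constant: for
half-max projection thresholding of a disk of radius R, the binary
sinogram's support is |s| ≤ (√3/2)R, and the unfiltered back-projection is
flat (=π) inside that support and decays as π − 2·arccos(r₀/ρ) outside, so
thresholding at fraction t recovers radius r₀/cos(π(1−t)/2) — exactly R at
t = 2/3. Filtered back-projection of a binary sinogram has a rim
singularity and no fraction that recovers the area (30–60 % bias in
practice). The ×2 upsampling removes whole-pixel quantization of the
half-width; measured accuracy is ≤ 0.3 px for diameters 10–40 px at zero
noise and ≤ 3 % at SNR 5 averaged over a 16-frame movie. Diameter is
D = 2√(area/π)·pixel size.

**FWHM.** Line-scan profiles are block-averaged over 100 ms, the baseline
is the median of the outer 10 % of samples on each side, and half-max
crossings are located by linear interpolation walking out from the peak.

**Dilation trace.** ΔD/D₀ with D₀ the pre-stimulus mean, after a zero-phase
(forward-backward) Chebyshev type-I low-pass: order 4, 0.5 dB ripple, 1 Hz
cutoff (heartbeat/breathing rejection). Zero-phase application squares the
magnitude response, so a 0.2-Hz physiological component is retained at
|H|² ≈ 0.94 — the tests assert against this frequency-response oracle
rather than unity.

## RBC velocimetry

Per 100-ms window (rounded to an **odd** number of lines) stepped by 20 ms:
de-mean, embed in an odd square canvas, Radon transform over a coarse
1° grid (−89…89°), refine at 0.1° around the variance maximum; the streak
angle from the time axis gives v = (Δx/Δt)·tanθ with sign = flow direction.
Windows with peak-to-mean variance contrast < 1.5 (no streaks) or |θ| > 88°
(out of measurable range) are NaN. The odd window/canvas choice makes the
discrete Radon variance profile exactly mirror-symmetric, so time-reversing
a line scan negates every velocity to machine precision — a useful
self-consistency check that even-sized grids break at the ~0.5 % level.
Subtraction of the static per-position background is available
(`remove_static=True`) but off by default, since it also erases genuinely
stalled cells (θ = 0).

The line-scan generator draws dark Gaussian-profile streaks (default width
2 px, depth 0.6, density 0.1 streaks/line) on a bright plasma background;
the streak slope in pixel units is exactly v·Δt/Δx. Streak-merging duty
cycles > 0.9 are recorded as warnings in the truth record.

## Functional maps

**Response maps** trial-average each pixel and apply the same
`response_metrics` function used for ROI traces — map/trace consistency is
bit-exact by construction, and tested as such. Pixels below `min_amplitude`
are invalid (NaN) and excluded from histograms.

**Fourier tonotopy.** The recording is trimmed to an integer number of
sweep periods; the DFT coefficient at 1/period gives per-pixel magnitude
and phase. Phase converts to a time within the sweep (after subtracting a
configurable response-delay offset, default 0), which is quantized to the
frame grid before slot assignment so responses on a tone-slot boundary are
not mis-binned by float round-off. The default protocol is five
amplitude-modulated tones (3, 6, 12, 24, 48 kHz), 0.2 s each at 3-s
intervals — a 15-s sweep.

**Pial-vessel mask.** Otsu threshold on log-reflectance (vessels are strong
absorbers → dark), morphological closing (radius 2); masks covering > 80 %
of the field raise (degenerate threshold). A `bright` mode handles
inverted-contrast inputs.

**NVCM.** For every non-vessel pixel, Pearson correlation with the regional
trace at every integer-frame lag within ±5 s (positive lag = hemodynamics
follow neurons); the lag maximizing |r| defines the lag map (sign of r is
preserved, so anticorrelation is detectable), the Pearson value the
normalized map, and the cross-covariance at that lag the un-normalized map.
Per-lag means and variances are recomputed on the actual overlap, so exact
shifted affine copies of the trace score r = 1 at the exact shift. Streams
at different rates are linearly interpolated onto the stack's frame grid.
`region_traces` (mask-averaged ΔF/F) stands in for factorization-based
decomposition of cortex-wide recordings, which is out of scope.

The NVC-session generator produces dHbT = gain·(trace ⊛ gamma-HRF)(t − lag)
with a gamma-variate HRF (shape 3, peak 1.5 s — the physiological hyperemic
delay scale). Two choices make the stated lag recoverable rather than
merely nominal: the HRF is applied **zero-phase** (forward-backward, i.e.
effectively its symmetric autocorrelation), because a causal skewed kernel
drags the correlation peak beyond the stated lag by its own group delay;
and the default session length is 1000 frames (100 s at 10 Hz, typical for
cortex-wide recordings), because the HRF-smoothed correlation peak is flat
enough that shorter records let finite-sample asymmetries wander the argmax
by 2–4 frames even at zero noise.

## What the synthetic tests do and do not show

The generators emulate the *structure* of each signal (stimulus-locked
transients, Beer-Lambert attenuation, exposure-integrated speckle
statistics, streak geometry, HRF-lagged hemodynamics) with additive
Gaussian noise only. They do not model photon shot noise, motion artifacts,
optical PSFs beyond Gaussian blur, indicator nonlinearity, vessel shapes
other than circular lumens, or pulsatile flow. Passing recovery tests
therefore establishes that the *analysis chain is a correct inverse of the
stated physical models at the stated noise levels* — not that those models
capture every property of in vivo recordings. Quantities that depend on
unknown constants (α, β, χ, T) are reported in proportional units
throughout and never silently converted.

## Problem sizes

Test and acceptance runs use 64×64 hemodynamic/speckle fields, 100-frame
reflectance stacks, 4-trial calcium sessions, 16-frame vessel movies,
601-line line scans and 1000-frame NVC sessions — sizes chosen so the full
verification suite completes in well under a minute while every estimator
operates far from small-sample degeneracy.
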