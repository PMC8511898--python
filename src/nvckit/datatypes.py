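"""Core data containers shared across the analysis stages.

All image data follow the ``(t, y, x)`` axis convention with 0-based pixel
centers. Containers are thin dataclasses around numpy arrays plus the
calibration metadata each stage needs; they validate their own invariants at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FrameStack",
    "LineScan",
    "RoiSet",
    "TraceSet",
    "StimulusProtocol",
    "GroundTruth",
    "HbMaps",
    "SpeckleContrastMap",
    "CbfMap",
    "DiameterTrace",
    "VelocityTrace",
    "ResponseMetrics",
    "ResponseMaps",
    "TonalMap",
    "NVCMaps",
]

#: Channel tags used by the multimodal acquisition.
CHANNELS = (
    "fluor_470",
    "reflect_530",
    "reflect_460",
    "speckle_635",
    "twophoton_green",
    "twophoton_red",
)

#: ROI roles recognised by trace extraction and vessel analysis.
ROI_ROLES = (
    "soma",
    "neuropil",
    "parenchyma",
    "small_artery",
    "large_artery",
    "small_vein",
    "large_vein",
    "vessel_lumen",
)


@dataclass
class FrameStack:
    """A ``(t, y, x)`` intensity movie with acquisition metadata.

    Parameters
    ----------
    data : ndarray
        Non-negative intensities, shape ``(t, y, x)``.
    frame_rate : float
        Frames per second (> 0).
    channel : str
        One of :data:`CHANNELS`.
    exposure_ms : float, optional
        Camera exposure per frame; must not exceed the frame interval.
    """

    data: np.ndarray
    frame_rate: float
    channel: str = "fluor_470"
    exposure_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"FrameStack data must be (t, y, x); got shape {self.data.shape}")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.exposure_ms is not None and self.exposure_ms > 1000.0 / self.frame_rate + 1e-9:
            raise ValueError("exposure_ms exceeds the frame interval")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class LineScan:
    """A ``(line, position)`` space-time image from repeated 1-D scanning."""

    data: np.ndarray
    dx_um_per_px: float
    dt_ms_per_line: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("LineScan data must be 2-D (line, position)")
        if self.data.shape[0] < 2:
            raise ValueError("LineScan needs at least 2 lines")
        if not (self.dx_um_per_px > 0 and self.dt_ms_per_line > 0):
            raise ValueError("dx_um_per_px and dt_ms_per_line must be > 0")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]


@dataclass
class RoiSet:
    """Integer label image plus a role for every label (0 = background)."""

    label_image: np.ndarray
    roles: dict[int, str]

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2-D")
        if not np.issubdtype(self.label_image.dtype, np.integer):
            raise ValueError("label_image must be integer-typed")
        labels = set(np.unique(self.label_image)) - {0}
        missing = labels - set(self.roles)
        if missing:
            raise ValueError(f"labels without a role: {sorted(missing)}")
        for lab, role in self.roles.items():
            if lab < 1:
                raise ValueError("ROI labels must be >= 1")
            if role not in ROI_ROLES:
                raise ValueError(f"unknown ROI role {role!r}")

    def labels(self) -> list[int]:
        return sorted(set(np.unique(self.label_image)) - {0})

    def mask(self, label: int) -> np.ndarray:
        return self.label_image == label


#: Allowed forward transitions of TraceSet.kind along the processing chain.
_KIND_ORDER = ("raw", "neuropil_corrected", "dff", "filtered", "trial_averaged")


@dataclass
class TraceSet:
    """Per-ROI time series at a common sampling rate."""

    traces: dict[int, np.ndarray]
    sampling_rate: float
    kind: str = "raw"
    trial_sem: Optional[dict[int, np.ndarray]] = None
    roles: Optional[dict[int, str]] = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown TraceSet kind {self.kind!r}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        self.traces = {int(k): np.asarray(v, dtype=float) for k, v in self.traces.items()}
        lengths = {v.shape[0] for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must have the same length")

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).shape[0] if self.traces else 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def derive(self, traces: dict[int, np.ndarray], kind: str, **kw) -> "TraceSet":
        """New TraceSet one step further along the processing chain."""
        if _KIND_ORDER.index(kind) < _KIND_ORDER.index(self.kind):
            raise ValueError(f"kind may not move backwards ({self.kind!r} -> {kind!r})")
        return TraceSet(traces, kw.pop("sampling_rate", self.sampling_rate), kind,
                        roles=self.roles, **kw)


@dataclass
class StimulusProtocol:
    """Stimulus timing: repeated presentations and (optionally) periodic sweeps.

    The tonal-mapping protocol presents a fixed set of amplitude-modulated
    tones in ascending order once per sweep; ``sweep_period_s`` must equal
    ``len(tone_frequencies_khz) * inter_stimulus_interval_s``.
    """

    onsets_s: np.ndarray
    duration_s: float = 0.2
    inter_stimulus_interval_s: float = 3.0
    sweep_period_s: Optional[float] = None
    tone_frequencies_khz: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be sorted and strictly increasing")
        if not self.duration_s < self.inter_stimulus_interval_s:
            raise ValueError("duration must be shorter than the inter-stimulus interval")
        if self.sweep_period_s is not None and self.tone_frequencies_khz is not None:
            expected = len(self.tone_frequencies_khz) * self.inter_stimulus_interval_s
            if abs(self.sweep_period_s - expected) > 1e-9:
                raise ValueError(
                    "sweep_period must equal n_tones * inter-stimulus interval "
                    f"({expected} s), got {self.sweep_period_s} s"
                )

    @classmethod
    def sam_tone_sweep(cls, n_sweeps: int = 16) -> "StimulusProtocol":
        """The five-tone ascending sweep protocol (3, 6, 12, 24, 48 kHz;
        0.2 s tones at 3-s intervals, 15-s sweep period)."""
        tones = (3.0, 6.0, 12.0, 24.0, 48.0)
        isi = 3.0
        period = len(tones) * isi
        onsets = np.arange(n_sweeps * len(tones)) * isi
        return cls(onsets, 0.2, isi, sweep_period_s=period, tone_frequencies_khz=tones)


@dataclass
class GroundTruth:
    """Truth record returned by every synthetic generator."""

    kind: str
    params: dict
    seed: int
    warnings: list[str] = field(default_factory=list)

    _KINDS = ("speckle", "reflectance", "calcium", "vessel", "linescan", "session", "tonal")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown GroundTruth kind {self.kind!r}")


@dataclass
class HbMaps:
    """Time-resolved hemoglobin-change maps.

    ``dHbT`` is α·ΔHbT (dimensionless) when ``units_flag == 'alpha_scaled'``
    and ΔHbT in µM when ``units_flag == 'molar'``. When the oxy/deoxy split is
    present, ``dHbT == dHbO2 + dHbR`` elementwise.
    """

    dHbT: np.ndarray
    units_flag: str = "alpha_scaled"
    dHbO2: Optional[np.ndarray] = None
    dHbR: Optional[np.ndarray] = None
    baseline_frames: Optional[np.ndarray] = None
    frame_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.units_flag not in ("alpha_scaled", "molar"):
            raise ValueError("units_flag must be 'alpha_scaled' or 'molar'")
        if (self.dHbO2 is None) != (self.dHbR is None):
            raise ValueError("dHbO2 and dHbR must be supplied together")
        if self.dHbO2 is not None:
            total = self.dHbO2 + self.dHbR
            if not np.allclose(np.nan_to_num(self.dHbT), np.nan_to_num(total),
                               rtol=1e-8, atol=1e-10):
                raise ValueError("dHbT must equal dHbO2 + dHbR")


@dataclass
class SpeckleContrastMap:
    """Spatial speckle contrast K = σ/μ per pixel (per frame)."""

    K: np.ndarray
    window_px: int
    exposure_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window_px % 2 == 0 or self.window_px < 3:
            raise ValueError("window_px must be odd and >= 3")


@dataclass
class CbfMap:
    """Blood-flow proxy 1/K² and relative change against a pre-stimulus baseline."""

    cbf_proxy: np.ndarray
    rel_change: Optional[np.ndarray] = None
    baseline_frames: Optional[np.ndarray] = None


@dataclass
class DiameterTrace:
    """Vessel diameter per frame/window plus relative dilation ΔD/D0."""

    diameter_um: np.ndarray
    times_s: np.ndarray
    method: str
    rel_dilation: Optional[np.ndarray] = None
    baseline_frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.method not in ("radon_area", "fwhm"):
            raise ValueError("method must be 'radon_area' or 'fwhm'")


@dataclass
class VelocityTrace:
    """RBC velocity per sliding window from line-scan streak angles."""

    velocity_mm_s: np.ndarray
    angle_deg: np.ndarray
    times_s: np.ndarray
    window_ms: float
    step_ms: float
    valid: Optional[np.ndarray] = None


@dataclass
class ResponseMetrics:
    """Onset/peak/amplitude of a trial-averaged stimulus response."""

    onset_time_s: float
    peak_time_s: float
    amplitude: float
    baseline: float = 0.0
    classification: str = "responsive"
    fit_slope: float = np.nan
    fit_intercept: float = np.nan
    fit_window: Optional[tuple[int, int]] = None
    fallback_interpolated: bool = False


@dataclass
class ResponseMaps:
    """Per-pixel response amplitude, peak time and onset time."""

    amplitude: np.ndarray
    peak_time_s: np.ndarray
    onset_time_s: np.ndarray
    valid_mask: np.ndarray


@dataclass
class TonalMap:
    """Fourier tonal (tonotopic) map: response phase, magnitude and preferred tone."""

    phase_rad: np.ndarray
    magnitude: np.ndarray
    preferred_tone_khz: np.ndarray
    sweep_period_s: float


@dataclass
class NVCMaps:
    """Neurovascular correlation maps against one regional neuronal trace."""

    xcorr: np.ndarray
    norm_xcorr: np.ndarray
    lag_time_s: np.ndarray
    lag_window_s: float
    region_id: Optional[int] = None
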