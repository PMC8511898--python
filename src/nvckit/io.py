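"""Readers, writers, configuration and registration plumbing.

Stacks travel as multipage TIFF with a YAML sidecar (``<name>.yaml``) holding
the acquisition metadata; traces and metrics as CSV; ground truth as JSON.
Pixel data are cast to float unchanged — no rescaling is applied on read, so
8-bit and 16-bit encodings of the same scene load to the same float values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .datatypes import FrameStack, LineScan, RoiSet, StimulusProtocol, TraceSet

__all__ = [
    "read_stack",
    "write_stack",
    "read_linescan",
    "write_linescan",
    "read_roi_set",
    "write_roi_set",
    "read_traces_csv",
    "write_traces_csv",
    "load_config",
    "config_hash",
    "read_protocol",
    "write_protocol",
    "register_translation",
]

log = logging.getLogger("nvckit")

_STACK_FIELDS = ("frame_rate",)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def read_stack(path, calibration: Optional[dict] = None) -> FrameStack:
    """Read a multipage TIFF into a :class:`FrameStack`.

    Metadata come from ``calibration`` or, if absent, from the YAML sidecar
    next to the file. ``frame_rate`` is required; ``channel`` and
    ``exposure_ms`` are optional.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a (t, y, x) stack, got shape {data.shape}")
    meta = dict(calibration or {})
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            file_meta = yaml.safe_load(fh) or {}
        for k, v in file_meta.items():
            meta.setdefault(k, v)
    missing = [f for f in _STACK_FIELDS if f not in meta]
    if missing:
        raise ValueError(f"{path}: missing calibration field(s) {missing}")
    return FrameStack(
        data.astype(np.float64),
        frame_rate=float(meta["frame_rate"]),
        channel=meta.get("channel", "fluor_470"),
        exposure_ms=meta.get("exposure_ms"),
    )


def write_stack(stack: FrameStack, path, dtype=None) -> Path:
    """Write a stack as multipage TIFF plus YAML sidecar; returns the path.

    With ``dtype=None`` pixel data are written as float64 (lossless); pass
    ``np.uint16`` for acquisition-style files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data if dtype is None else np.asarray(stack.data, dtype=dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"frame_rate": float(stack.frame_rate), "channel": stack.channel}
    if stack.exposure_ms is not None:
        meta["exposure_ms"] = float(stack.exposure_ms)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_linescan(path, calibration: Optional[dict] = None) -> LineScan:
    path = Path(path)
    data = tifffile.imread(path)
    meta = dict(calibration or {})
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            for k, v in (yaml.safe_load(fh) or {}).items():
                meta.setdefault(k, v)
    for f in ("dx_um_per_px", "dt_ms_per_line"):
        if f not in meta:
            raise ValueError(f"{path}: missing calibration field {f!r}")
    return LineScan(data.astype(np.float64), float(meta["dx_um_per_px"]),
                    float(meta["dt_ms_per_line"]))


def write_linescan(scan: LineScan, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, scan.data, photometric="minisblack")
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({"dx_um_per_px": scan.dx_um_per_px,
                        "dt_ms_per_line": scan.dt_ms_per_line}, fh)
    return path


def read_roi_set(path, roles: Optional[dict[int, str]] = None) -> RoiSet:
    """Read an integer label image (TIFF/PNG); roles from arg or JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        label = np.asarray(tifffile.imread(path))
    else:
        import imageio.v3 as iio

        label = np.asarray(iio.imread(path))
    side = path.with_suffix(".json")
    if roles is None and side.exists():
        with open(side) as fh:
            roles = {int(k): v for k, v in json.load(fh).items()}
    return RoiSet(label.astype(np.int32), roles or {})


def write_roi_set(roi: RoiSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, roi.label_image.astype(np.int32))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({str(k): v for k, v in roi.roles.items()}, fh)
    return path


def write_traces_csv(ts: TraceSet, path) -> Path:
    """Long-format CSV: roi_id, role, time_s, value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = ts.times
    rows = []
    for roi_id, tr in ts.traces.items():
        role = (ts.roles or {}).get(roi_id, "")
        rows.append(pd.DataFrame({"roi_id": roi_id, "role": role, "time_s": t, "value": tr}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


def read_traces_csv(path, sampling_rate: Optional[float] = None,
                    kind: str = "raw") -> TraceSet:
    df = pd.read_csv(path)
    traces, roles = {}, {}
    for roi_id, g in df.groupby("roi_id"):
        g = g.sort_values("time_s")
        traces[int(roi_id)] = g["value"].to_numpy()
        role = str(g["role"].iloc[0])
        if role and role != "nan":
            roles[int(roi_id)] = role
    if sampling_rate is None:
        t = df[df.roi_id == df.roi_id.iloc[0]]["time_s"].to_numpy()
        sampling_rate = 1.0 / float(np.median(np.diff(np.sort(t))))
    return TraceSet(traces, sampling_rate, kind, roles=roles or None)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for run logging."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_protocol(path) -> StimulusProtocol:
    cfg = load_config(path)
    return StimulusProtocol(
        np.asarray(cfg["onsets_s"], dtype=float),
        duration_s=float(cfg.get("duration_s", 0.2)),
        inter_stimulus_interval_s=float(cfg.get("inter_stimulus_interval_s", 3.0)),
        sweep_period_s=cfg.get("sweep_period_s"),
        tone_frequencies_khz=tuple(cfg["tone_frequencies_khz"])
        if cfg.get("tone_frequencies_khz") else None,
    )


def write_protocol(protocol: StimulusProtocol, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = {
        "onsets_s": [float(x) for x in protocol.onsets_s],
        "duration_s": protocol.duration_s,
        "inter_stimulus_interval_s": protocol.inter_stimulus_interval_s,
    }
    if protocol.sweep_period_s is not None:
        cfg["sweep_period_s"] = float(protocol.sweep_period_s)
    if protocol.tone_frequencies_khz is not None:
        cfg["tone_frequencies_khz"] = [float(x) for x in protocol.tone_frequencies_khz]
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return path


def register_translation(stack: FrameStack, reference_frame_index: int = 0,
                         upsample_factor: int = 10):
    """Translation-only motion correction by phase correlation.

    Each frame is registered against the reference frame; the estimated
    (dy, dx) shifts are applied by spline interpolation and returned as a
    table for audit. Zero-variance frames get shift (0, 0) with a warning.

    Returns
    -------
    (FrameStack, ndarray)
        Registered stack and the ``(n_frames, 2)`` shift table.
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = stack.data[reference_frame_index]
    shifts = np.zeros((stack.n_frames, 2))
    out = np.empty_like(stack.data, dtype=float)
    for i, frame in enumerate(stack.data):
        if i == reference_frame_index:
            out[i] = frame
            continue
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            log.warning("frame %d has zero variance; shift set to 0", i)
            out[i] = frame
            continue
        corr, _, _ = phase_cross_correlation(ref, frame, upsample_factor=upsample_factor)
        shifts[i] = -corr  # the frame's displacement relative to the reference
        out[i] = ndimage.shift(frame, corr, order=1, mode="nearest")
    reg = FrameStack(out, stack.frame_rate, stack.channel, stack.exposure_ms)
    return reg, shifts
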