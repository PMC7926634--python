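"""Respiratory-rate extraction from chest motion in thermal sequences.

Pipeline: buffer four consecutive chest crops, average the first three
and the last three pixel-wise to suppress sensor noise, compute dense
optical flow between the two averaged crops, spatially average the
displacement field into one motion sample per frame, bandpass the
resulting series to the physiological breathing band, and pick the
largest autocorrelation peak inside that band as the breathing period.

The 4-frame buffer slides by one frame, yielding ``n - 3`` motion
samples for ``n`` frames.  Filtering is zero-phase (forward-backward):
the analysis is retrospective per window and phase distortion would
skew the autocorrelation peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .irt_io import BoundingBox, RoiTrack, ThermalSequence, crop, normalize_frame
from .optflow import FlowParams, build_pyramid, expand_pyramid, flow_from_expansions

__all__ = [
    "RespirationConfig",
    "MotionSignal",
    "RREstimate",
    "temporal_filter",
    "chest_motion_signal",
    "bandpass",
    "autocorrelation",
    "estimate_rr",
    "extract_rr",
]

#: quality flags attached to individual motion samples
FLAG_CLINICIAN = "clinician_overlap"
FLAG_GAP = "detection_gap"
FLAG_CLIPPED = "clipped_roi"


@dataclass(frozen=True)
class RespirationConfig:
    """Sampling, band, window and exclusion settings for RR extraction."""

    fs: float = 4.0
    band_low: float = 0.15
    band_high: float = 0.44
    filter_order: int = 2
    window_frames: int = 960  # ~240 s at 4 fps
    flow_params: FlowParams = field(default_factory=FlowParams)
    motion_axis: str = "auto"  # {"x", "y", "auto"}
    peak_floor: float = 0.2  # minimum normalized ACF peak for a valid estimate
    motion_floor_px: float = 0.01  # minimum raw-signal std; below = no chest motion
    overlap_cap: float = 0.5  # max tolerated clinician-overlap fraction per window
    max_gap_frames: int = 2  # detection gaps bridged by the last box up to this length
    max_invalid_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.fs / 2):
            raise ValueError("need 0 < band_low < band_high < fs/2")
        if self.window_frames < 4:
            raise ValueError("window_frames must be >= 4")
        if self.motion_axis not in ("x", "y", "auto"):
            raise ValueError(f"motion_axis must be x, y or auto, got {self.motion_axis!r}")


@dataclass
class MotionSignal:
    """Spatially averaged chest displacement, one sample per frame pair."""

    values: np.ndarray
    timestamps: np.ndarray
    flags: list[set[str]]
    valid: np.ndarray
    axis: str = "y"

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.timestamps) == len(self.flags) == len(self.valid) == n):
            raise ValueError("motion-signal component lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    def overlap_fraction(self) -> float:
        if len(self.flags) == 0:
            return 0.0
        return sum(FLAG_CLINICIAN in f for f in self.flags) / len(self.flags)


@dataclass
class RREstimate:
    """Outcome of one analysis window; invalid estimates carry a reason."""

    rr_bpm: float
    peak_lag: float  # seconds
    peak_value: float
    valid: bool
    exclusion_reason: str | None = None
    overlap_fraction: float = 0.0


def temporal_filter(frames: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Average a 4-frame buffer into the two optical-flow inputs.

    ``prev = mean(f[t-2], f[t-1], f[t])`` and
    ``next = mean(f[t-1], f[t], f[t+1])``, pixel-wise.
    """
    if len(frames) != 4:
        raise ValueError(f"temporal filter needs exactly 4 frames, got {len(frames)}")
    grids = [np.asarray(f, dtype=np.float64) for f in frames]
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("buffer frames have mismatched shapes")
    prev_avg = (grids[0] + grids[1] + grids[2]) / 3.0
    next_avg = (grids[1] + grids[2] + grids[3]) / 3.0
    return prev_avg, next_avg


def _resolve_boxes(
    track: RoiTrack, n_frames: int, cfg: RespirationConfig
) -> tuple[list[BoundingBox | None], list[set[str]]]:
    """Chest box per frame with short gaps bridged by the last seen box."""
    boxes: list[BoundingBox | None] = []
    flags: list[set[str]] = []
    last: BoundingBox | None = None
    gap = 0
    for i in range(n_frames):
        frame_flags: set[str] = set()
        chest = track.boxes(i, "chest")
        if chest:
            # highest-confidence chest box wins when several are present
            box = max(chest, key=lambda b: b.confidence if b.confidence is not None else 1.0)
            last, gap = box, 0
        else:
            gap += 1
            frame_flags.add(FLAG_GAP)
            box = last if (last is not None and gap <= cfg.max_gap_frames) else None
        for clin in track.boxes(i, "clinician"):
            if box is not None and clin.intersects(box):
                frame_flags.add(FLAG_CLINICIAN)
        boxes.append(box)
        flags.append(frame_flags)
    return boxes, flags


def chest_motion_signal(
    seq: ThermalSequence, track: RoiTrack, cfg: RespirationConfig | None = None
) -> MotionSignal:
    """Per-frame mean chest displacement with quality flags.

    For each sliding 4-frame buffer the chest crop of the buffer's
    reference frame is applied to all four frames, the temporal filter
    produces the flow input pair, and the flow field is averaged over
    the crop.  Consecutive buffers reuse the shared averaged crop, so
    each frame's polynomial expansion is computed once when the box is
    stable.
    """
    cfg = cfg or RespirationConfig()
    n = len(seq)
    if n < 4:
        raise ValueError(f"need at least 4 frames, got {n}")
    h, w = seq.shape
    boxes, frame_flags = _resolve_boxes(track, n, cfg)

    values_x: list[float] = []
    values_y: list[float] = []
    timestamps: list[float] = []
    flags: list[set[str]] = []
    valid: list[bool] = []

    cache_box: BoundingBox | None = None
    cache_next: tuple | None = None  # (pyramid shapes, expansions) of previous next_avg

    for t in range(2, n - 1):
        box = boxes[t]
        sample_flags = frame_flags[t - 2] | frame_flags[t - 1] | frame_flags[t] | frame_flags[t + 1]
        timestamps.append(seq.frames[t].timestamp)
        if box is None:
            values_x.append(0.0)
            values_y.append(0.0)
            flags.append(sample_flags | {FLAG_GAP})
            valid.append(False)
            cache_box = None
            continue
        clamped, clipped = box.clip(w, h)
        if clipped:
            sample_flags.add(FLAG_CLIPPED)

        same_box = cache_box is not None and clamped == cache_box and cache_next is not None
        if same_box:
            shapes, exps_prev = cache_next  # previous buffer's next_avg == this prev_avg
        else:
            crops = [crop(seq.frames[i].values, clamped) for i in (t - 2, t - 1, t)]
            prev_avg = normalize_frame(sum(crops) / 3.0)
            pyr = build_pyramid(prev_avg, cfg.flow_params)
            shapes = [p.shape for p in pyr]
            exps_prev = expand_pyramid(pyr, cfg.flow_params)
        crops_next = [crop(seq.frames[i].values, clamped) for i in (t - 1, t, t + 1)]
        next_avg = normalize_frame(sum(crops_next) / 3.0)
        pyr_next = build_pyramid(next_avg, cfg.flow_params)
        exps_next = expand_pyramid(pyr_next, cfg.flow_params)

        flow = flow_from_expansions(exps_prev, exps_next, shapes, cfg.flow_params)
        values_x.append(float(flow.dx.mean()))
        values_y.append(float(flow.dy.mean()))
        flags.append(sample_flags)
        valid.append(True)
        cache_box = clamped
        cache_next = (shapes, exps_next)

    vx = np.array(values_x)
    vy = np.array(values_y)
    axis = cfg.motion_axis
    if axis == "auto":
        ok = np.array(valid)
        axis = "y" if np.var(vy[ok]) >= np.var(vx[ok]) else "x" if ok.any() else "y"
    return MotionSignal(
        values=vx if axis == "x" else vy,
        timestamps=np.array(timestamps),
        flags=flags,
        valid=np.array(valid),
        axis=axis,
    )


def _design_sos(cfg: RespirationConfig) -> np.ndarray:
    return signal.butter(
        cfg.filter_order, [cfg.band_low, cfg.band_high], btype="bandpass", fs=cfg.fs, output="sos"
    )


def _min_length(sos: np.ndarray) -> int:
    # forward-backward filtering pads by 3x the effective impulse length
    padlen = 3 * (2 * len(sos) + 1)
    return 3 * padlen


def bandpass(sig: MotionSignal, cfg: RespirationConfig | None = None) -> MotionSignal:
    """Zero-phase Butterworth bandpass to the breathing band, mean removed."""
    cfg = cfg or RespirationConfig()
    sos = _design_sos(cfg)
    x = np.asarray(sig.values, dtype=np.float64)
    if len(x) < _min_length(sos):
        raise ValueError(f"signal too short for bandpass: {len(x)} < {_min_length(sos)} samples")
    y = signal.sosfiltfilt(sos, x - x.mean())
    y = y - y.mean()
    return MotionSignal(
        values=y, timestamps=sig.timestamps, flags=sig.flags, valid=sig.valid, axis=sig.axis
    )


def autocorrelation(sig: MotionSignal | np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased sample autocorrelation normalized to ``r(0) = 1``.

    The biased estimator (dividing by ``n``) damps long-lag noise peaks,
    which is what peak picking wants.  Raises on zero-variance input.
    """
    x = np.asarray(sig.values if isinstance(sig, MotionSignal) else sig, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("autocorrelation needs at least 2 samples")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("zero-variance signal: autocorrelation undefined")
    full = signal.correlate(x, x, mode="full", method="auto")
    acf = full[n - 1 :] / denom
    if max_lag is not None:
        acf = acf[: max_lag + 1]
    return acf


def estimate_rr(acf: np.ndarray, cfg: RespirationConfig | None = None) -> RREstimate:
    """Pick the largest in-band autocorrelation peak and convert to bpm.

    Local maxima are searched at lags within ``[1/band_high, 1/band_low]``
    seconds; the winning lag is refined by three-point parabolic
    interpolation (the integer lag grid at 4 fps is far too coarse for
    sub-bpm resolution).  An estimate whose peak falls below
    ``peak_floor`` is returned invalid rather than raising.
    """
    cfg = cfg or RespirationConfig()
    acf = np.asarray(acf, dtype=np.float64)
    k_lo = int(np.ceil(cfg.fs / cfg.band_high))
    k_hi = int(np.floor(cfg.fs / cfg.band_low))
    k_hi = min(k_hi, len(acf) - 2)
    candidates: list[tuple[int, float, float]] = []  # (k, refined delta, refined value)
    for k in range(max(k_lo, 1), k_hi + 1):
        if acf[k] > acf[k - 1] and acf[k] >= acf[k + 1]:
            y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            candidates.append((k, delta, float(y1 - 0.25 * (y0 - y2) * delta)))
    if not candidates:
        return RREstimate(
            rr_bpm=float("nan"), peak_lag=float("nan"), peak_value=float("nan"),
            valid=False, exclusion_reason="no_inband_peak",
        )
    # A period-T signal also peaks at lag 2T; refined values of the
    # fundamental and its subharmonic differ only by the lag taper, so
    # prefer the shortest lag among peaks within 5% of the best.
    best = max(v for _, _, v in candidates)
    floor = best - 0.05 * abs(best)
    best_k, delta, peak_value = min(
        (c for c in candidates if c[2] >= floor), key=lambda c: c[0]
    )
    lag_s = (best_k + delta) / cfg.fs
    lag_s = float(np.clip(lag_s, 1.0 / cfg.band_high, 1.0 / cfg.band_low))
    if peak_value < cfg.peak_floor:
        return RREstimate(
            rr_bpm=60.0 / lag_s, peak_lag=lag_s, peak_value=peak_value,
            valid=False, exclusion_reason="peak_below_floor",
        )
    return RREstimate(
        rr_bpm=60.0 / lag_s, peak_lag=lag_s, peak_value=peak_value, valid=True
    )


def _bridge_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate samples lost to long detection gaps."""
    if valid.all():
        return values
    idx = np.arange(len(values))
    return np.interp(idx, idx[valid], values[valid])


def extract_rr(
    seq: ThermalSequence, track: RoiTrack, cfg: RespirationConfig | None = None
) -> RREstimate:
    """End-to-end RR estimate over the configured analysis window."""
    cfg = cfg or RespirationConfig()
    n = min(len(seq), cfg.window_frames)
    window = ThermalSequence(frames=seq.frames[:n], fps=seq.fps, meta=seq.meta)
    sig = chest_motion_signal(window, track, cfg)
    overlap = sig.overlap_fraction()

    def invalid(reason: str) -> RREstimate:
        return RREstimate(
            rr_bpm=float("nan"), peak_lag=float("nan"), peak_value=float("nan"),
            valid=False, exclusion_reason=reason, overlap_fraction=overlap,
        )

    if overlap > cfg.overlap_cap:
        return invalid(FLAG_CLINICIAN)
    if not sig.valid.any() or (1.0 - sig.valid.mean()) > cfg.max_invalid_fraction:
        return invalid(FLAG_GAP)
    raw = _bridge_invalid(sig.values, sig.valid)
    if raw.std() < cfg.motion_floor_px:
        return invalid("low_motion")
    filtered = bandpass(
        MotionSignal(raw, sig.timestamps, sig.flags, sig.valid, sig.axis), cfg
    )
    try:
        acf = autocorrelation(filtered)
    except ValueError:
        return invalid("zero_variance")
    est = estimate_rr(acf, cfg)
    est.overlap_fraction = overlap
    return est
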