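"""Head-surface temperature trends with ambient-drift compensation.

The sensor's thermal sensitivity (40 mK) is far better than its
absolute accuracy (about +/-2 degrees C), so absolute temperatures are
never reported as clinical values — only deviations from the first
measurement point.  Camera/room drift is compensated by subtracting the
ambient estimate (mean of a small corner ROI) from the head reading
before differencing, which cancels any common additive drift exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .irt_io import BoundingBox, RoiTrack, ThermalFrame, ThermalSequence, crop

__all__ = [
    "TemperatureConfig",
    "TrendSeries",
    "RegressionResult",
    "head_temperature",
    "ambient_estimate",
    "trend",
    "trend_regression",
]


@dataclass(frozen=True)
class TemperatureConfig:
    """Ambient ROI, aggregation length, and the fixed head statistic (max)."""

    ambient_roi: tuple[int, int, int, int] = (0, 0, 5, 5)  # (x0, y0, x1, y1) upper-left corner
    aggregation_frames: int = 240

    def __post_init__(self) -> None:
        if self.aggregation_frames < 1:
            raise ValueError("aggregation_frames must be >= 1")
        x0, y0, x1, y1 = self.ambient_roi
        if not (0 <= x0 < x1 and 0 <= y0 < y1):
            raise ValueError(f"bad ambient_roi {self.ambient_roi}")


@dataclass
class TrendSeries:
    """Per-measurement-point head temperature deviations.

    ``deviation_raw`` differences the head maxima against the first
    valid point; ``deviation_corrected`` subtracts the ambient estimate
    per point before differencing.  Missing points (no head box in any
    of their frames) are flagged, never interpolated.
    """

    times: np.ndarray
    head_max: np.ndarray
    ambient: np.ndarray
    deviation_raw: np.ndarray
    deviation_corrected: np.ndarray
    n_frames: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        lengths = {
            len(self.times), len(self.head_max), len(self.ambient),
            len(self.deviation_raw), len(self.deviation_corrected),
            len(self.n_frames), len(self.missing),
        }
        if len(lengths) != 1:
            raise ValueError("trend-series component lengths differ")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    mse: float
    r_squared: float
    r: float


def head_temperature(frame: ThermalFrame | np.ndarray, head_box: BoundingBox) -> float:
    """Maximum temperature inside the (cropped) head bounding box."""
    return float(crop(frame, head_box).max())


def ambient_estimate(frame: ThermalFrame | np.ndarray, cfg: TemperatureConfig | None = None) -> float:
    """Room-temperature proxy: mean of the configured corner ROI."""
    cfg = cfg or TemperatureConfig()
    x0, y0, x1, y1 = cfg.ambient_roi
    values = frame.values if isinstance(frame, ThermalFrame) else np.asarray(frame)
    return float(values[y0:y1, x0:x1].mean())


def trend(
    seq: ThermalSequence, track: RoiTrack, cfg: TemperatureConfig | None = None
) -> TrendSeries:
    """Aggregate per-frame head maxima into a deviation trend.

    Frames are partitioned into consecutive measurement points of
    ``aggregation_frames`` each.  Within a point, the head statistic is
    the mean over frames that have a head box of the per-frame maximum;
    the ambient estimate is averaged over all frames of the point.
    """
    cfg = cfg or TemperatureConfig()
    n = len(seq)
    k = cfg.aggregation_frames
    n_points = (n + k - 1) // k
    times = np.empty(n_points)
    head_max = np.full(n_points, np.nan)
    ambient = np.empty(n_points)
    n_frames = np.zeros(n_points, dtype=int)
    missing = np.zeros(n_points, dtype=bool)

    for p in range(n_points):
        lo, hi = p * k, min((p + 1) * k, n)
        frames = seq.frames[lo:hi]
        times[p] = float(np.mean([f.timestamp for f in frames]))
        ambient[p] = float(np.mean([ambient_estimate(f, cfg) for f in frames]))
        maxima = []
        for i in range(lo, hi):
            head_boxes = track.boxes(i, "head")
            if head_boxes:
                box = max(
                    head_boxes,
                    key=lambda b: b.confidence if b.confidence is not None else 1.0,
                )
                maxima.append(head_temperature(seq.frames[i], box))
        n_frames[p] = len(maxima)
        if maxima:
            head_max[p] = float(np.mean(maxima))
        else:
            missing[p] = True

    valid_idx = np.flatnonzero(~missing)
    if valid_idx.size == 0:
        raise ValueError("no measurement point contains a head box")
    ref = valid_idx[0]
    deviation_raw = head_max - head_max[ref]
    deviation_corrected = (head_max - ambient) - (head_max[ref] - ambient[ref])
    deviation_raw[missing] = np.nan
    deviation_corrected[missing] = np.nan
    return TrendSeries(
        times=times,
        head_max=head_max,
        ambient=ambient,
        deviation_raw=deviation_raw,
        deviation_corrected=deviation_corrected,
        n_frames=n_frames,
        missing=missing,
    )


def trend_regression(estimates: np.ndarray, reference: np.ndarray) -> RegressionResult:
    """OLS of the reference series on the camera estimate.

    Returns slope/intercept of ``reference ~ estimate`` plus residual
    MSE, coefficient of determination, and Pearson r.
    """
    x = np.asarray(estimates, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance estimate series")
    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    mse = float(np.mean(residuals**2))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        mse=mse,
        r_squared=float(fit.rvalue**2),
        r=float(fit.rvalue),
    )
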