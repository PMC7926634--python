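"""Clinician-attendance quantification.

Presence is binary per frame (any clinician box counts); the daily
profile pools presence samples from all days and patients into
time-of-day bins and reports percent presence per bin, where 100 means
continuous presence.  Bins without samples are filled by linear
interpolation that wraps around midnight.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np

from .irt_io import RoiTrack

__all__ = ["AttendanceSeries", "DailyProfile", "presence_series", "daily_profile"]

_DAY_S = 86400


@dataclass
class AttendanceSeries:
    """Binary clinician presence per frame, with absolute timestamps."""

    timestamps: np.ndarray  # seconds; interpreted modulo 24 h for the profile
    present: np.ndarray

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.present):
            raise ValueError("timestamps/present length mismatch")
        if not np.isin(self.present, (0, 1)).all():
            raise ValueError("present must be binary")

    def __len__(self) -> int:
        return len(self.present)

    def concat(self, other: "AttendanceSeries") -> "AttendanceSeries":
        return AttendanceSeries(
            timestamps=np.concatenate([self.timestamps, other.timestamps]),
            present=np.concatenate([self.present, other.present]),
        )


@dataclass
class DailyProfile:
    """Percent presence per time-of-day bin, pooled across days."""

    bin_start_min: np.ndarray  # minutes after midnight
    percent: np.ndarray  # in [0, 100]; empty bins interpolated
    n_samples: np.ndarray
    interpolated: np.ndarray  # True where the bin had no samples


def _to_seconds(timestamps: Sequence) -> np.ndarray:
    first = timestamps[0] if len(timestamps) else 0.0
    if isinstance(first, (datetime, np.datetime64)) or (
        hasattr(timestamps, "dtype") and np.issubdtype(np.asarray(timestamps).dtype, np.datetime64)
    ):
        ts = np.asarray(timestamps, dtype="datetime64[s]")
        return (ts - ts.astype("datetime64[D]")).astype(np.float64)
    return np.asarray(timestamps, dtype=np.float64)


def presence_series(track: RoiTrack, timestamps: Sequence) -> AttendanceSeries:
    """present[i] = 1 iff frame i has at least one clinician box."""
    seconds = _to_seconds(timestamps)
    n = len(seconds)
    if track.entries and max(track.entries) >= n:
        raise ValueError(
            f"{n} timestamps but track has frame index {max(track.entries)}"
        )
    present = np.zeros(n, dtype=np.int8)
    for i in range(n):
        if any(b.label == "clinician" for b in track.boxes(i)):
            present[i] = 1
    return AttendanceSeries(timestamps=seconds, present=present)


def daily_profile(series: AttendanceSeries, bin_minutes: int = 60) -> DailyProfile:
    """Pool presence samples into circular time-of-day bins."""
    if len(series) == 0:
        raise ValueError("need at least one presence sample")
    if 1440 % bin_minutes != 0:
        raise ValueError(f"bin_minutes must divide 1440, got {bin_minutes}")
    n_bins = 1440 // bin_minutes
    second_of_day = np.mod(series.timestamps, _DAY_S)
    bins = (second_of_day // (bin_minutes * 60)).astype(int)
    n_samples = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=series.present, minlength=n_bins)
    percent = np.full(n_bins, np.nan)
    nonempty = n_samples > 0
    percent[nonempty] = 100.0 * sums[nonempty] / n_samples[nonempty]

    interpolated = ~nonempty
    if interpolated.any():
        centers = (np.arange(n_bins) + 0.5) * bin_minutes
        xp = centers[nonempty]
        fp = percent[nonempty]
        # wrap the known points around both ends for circular interpolation
        xp_ext = np.concatenate([xp - 1440.0, xp, xp + 1440.0])
        fp_ext = np.concatenate([fp, fp, fp])
        percent[interpolated] = np.interp(centers[interpolated], xp_ext, fp_ext)

    return DailyProfile(
        bin_start_min=np.arange(n_bins) * bin_minutes,
        percent=percent,
        n_samples=n_samples,
        interpolated=interpolated,
    )
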