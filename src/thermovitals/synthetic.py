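"""Seeded generator of radiometric thermal scenes with exact ground truth.

Renders a warm patient on a cool background: a body blob, a head
ellipse whose core temperature may drift over time, and a textured
chest rectangle displaced vertically by a breathing waveform.  Ambient
drift, additive Gaussian sensor noise (40 mK class) and transient
clinician blobs complete the measurement model.  All temporally varying
structures are evaluated analytically at sub-pixel positions, so
sub-pixel optical flow on the rendered frames is physically meaningful.

Randomness comes exclusively from ``numpy.random.default_rng`` (PCG64),
so identical seeds give bit-identical scenes across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .irt_io import BoundingBox, RoiTrack, ThermalFrame, ThermalSequence

__all__ = [
    "HeadConfig",
    "ChestConfig",
    "ClinicianEvent",
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "generate_detection_fixture",
]


@dataclass(frozen=True)
class HeadConfig:
    center: tuple[float, float] = (0.5, 0.22)  # fractional (x, y)
    axes: tuple[float, float] = (0.09, 0.11)  # fractional semi-axes
    core_temp: float = 36.8
    temp_trend: float = 0.0  # K/h


@dataclass(frozen=True)
class ChestConfig:
    center: tuple[float, float] = (0.5, 0.52)
    size: tuple[float, float] = (0.32, 0.22)  # fractional (w, h)
    temp: float = 33.0
    rr_bpm: float = 15.0
    amplitude_px: float = 1.0
    waveform: str = "sine"  # {"sine", "sine+harmonic"}
    texture_period_px: float = 12.0
    texture_amplitude: float = 1.2  # K


@dataclass(frozen=True)
class ClinicianEvent:
    start_s: float
    end_s: float
    center: tuple[float, float] = (0.22, 0.5)
    size: tuple[float, float] = (0.18, 0.45)
    temp: float = 34.0
    overlap_chest: bool = False


@dataclass(frozen=True)
class SceneConfig:
    width: int = 382
    height: int = 288
    fps: float = 4.0
    duration: float = 240.0
    background_temp: float = 21.0
    ambient_drift: float = 0.0  # K/h
    head: HeadConfig = field(default_factory=HeadConfig)
    chest: ChestConfig = field(default_factory=ChestConfig)
    clinician_events: tuple[ClinicianEvent, ...] = ()
    noise_sigma: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        for cx, cy in (self.head.center, self.chest.center):
            if not (0 < cx < 1 and 0 < cy < 1):
                raise ValueError("geometry centers must lie inside the frame")

    @property
    def n_frames(self) -> int:
        return max(int(round(self.duration * self.fps)), 1)


@dataclass
class SceneTruth:
    """Exact per-frame ground truth emitted next to the rendered frames."""

    boxes: RoiTrack
    rr_bpm: float
    head_trend: np.ndarray  # K deviation from t=0, per frame
    ambient_series: np.ndarray  # degrees C per frame
    clinician_presence: np.ndarray  # {0,1} per frame
    chest_shift: np.ndarray  # px vertical displacement per frame


def _smooth_rect(
    xx: np.ndarray, yy: np.ndarray, x0: float, x1: float, y0: float, y1: float, edge: float
) -> np.ndarray:
    """Soft indicator of a rectangle with tanh edges of width ``edge`` px."""
    ex = 0.5 * (np.tanh((xx - x0) / edge) - np.tanh((xx - x1) / edge))
    ey = 0.5 * (np.tanh((yy - y0) / edge) - np.tanh((yy - y1) / edge))
    return ex * ey


def _plateau_ellipse(
    xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, ax: float, ay: float
) -> np.ndarray:
    """Elliptical bump: exactly 1 inside 60% of the radius, smooth outside."""
    r = np.sqrt(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2)
    env = np.clip((1.2 - r) / 0.6, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * env)  # cosine-smooth step, plateau at 1


def _blend(frame: np.ndarray, env: np.ndarray, target: np.ndarray | float) -> np.ndarray:
    return frame + env * (target - frame)


def _breathing_shift(cfg: ChestConfig, t: np.ndarray | float) -> np.ndarray | float:
    phase = 2.0 * math.pi * (cfg.rr_bpm / 60.0) * t
    s = np.sin(phase)
    if cfg.waveform == "sine+harmonic":
        s = s + 0.3 * np.sin(2.0 * phase)
    elif cfg.waveform != "sine":
        raise ValueError(f"unknown waveform {cfg.waveform!r}")
    return cfg.amplitude_px * s


def generate_scene(cfg: SceneConfig) -> tuple[ThermalSequence, SceneTruth]:
    """Render the configured scene and its exact ground truth."""
    w, h = cfg.width, cfg.height
    n = cfg.n_frames
    rng = np.random.default_rng(cfg.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    t = np.arange(n) / cfg.fps
    t_hours = t / 3600.0

    head_cx, head_cy = cfg.head.center[0] * w, cfg.head.center[1] * h
    head_ax, head_ay = cfg.head.axes[0] * w, cfg.head.axes[1] * h
    chest_cx, chest_cy = cfg.chest.center[0] * w, cfg.chest.center[1] * h
    chest_w, chest_h = cfg.chest.size[0] * w, cfg.chest.size[1] * h

    # static envelopes
    body_env = _smooth_rect(
        xx, yy,
        chest_cx - chest_w * 0.75, chest_cx + chest_w * 0.75,
        head_cy - head_ay * 1.5, min(chest_cy + chest_h * 2.2, h - 2.0),
        edge=4.0,
    )
    head_env = _plateau_ellipse(xx, yy, head_cx, head_cy, head_ax, head_ay)
    chest_x0 = chest_cx - chest_w / 2
    chest_x1 = chest_cx + chest_w / 2
    chest_y0 = chest_cy - chest_h / 2
    chest_y1 = chest_cy + chest_h / 2
    lam = cfg.chest.texture_period_px

    shifts = np.asarray(_breathing_shift(cfg.chest, t), dtype=np.float64) * np.ones(n)
    ambient = cfg.background_temp + cfg.ambient_drift * t_hours
    head_trend = cfg.head.temp_trend * t_hours

    events = list(cfg.clinician_events)
    ev_geo = []
    for ev in events:
        if ev.overlap_chest:
            ecx, ecy = chest_cx - chest_w * 0.25, chest_cy
        else:
            ecx, ecy = ev.center[0] * w, ev.center[1] * h
        ev_geo.append((ecx, ecy, ev.size[0] * w / 2, ev.size[1] * h / 2))

    track = RoiTrack()
    presence = np.zeros(n, dtype=np.int8)
    frames: list[ThermalFrame] = []

    # static truth boxes (annotation-style: enclose the moving chest)
    margin = abs(cfg.chest.amplitude_px) + 3.0
    chest_box = BoundingBox(
        "chest",
        x_min=math.floor(chest_x0 - 3), y_min=math.floor(chest_y0 - margin),
        x_max=math.ceil(chest_x1 + 3), y_max=math.ceil(chest_y1 + margin),
    )
    head_box = BoundingBox(
        "head",
        x_min=math.floor(head_cx - head_ax - 2), y_min=math.floor(head_cy - head_ay - 2),
        x_max=math.ceil(head_cx + head_ax + 2), y_max=math.ceil(head_cy + head_ay + 2),
    )
    patient_box = BoundingBox(
        "patient",
        x_min=max(math.floor(chest_cx - chest_w * 0.8), 0),
        y_min=max(math.floor(head_cy - head_ay * 1.8), 0),
        x_max=min(math.ceil(chest_cx + chest_w * 0.8), w),
        y_max=min(math.ceil(chest_cy + chest_h * 2.4), h),
    )

    for i in range(n):
        frame = np.full((h, w), cfg.background_temp, dtype=np.float64)
        frame = _blend(frame, body_env, 30.5)

        # chest: the whole pattern (edges + texture) rides on the shift
        s = shifts[i]
        ys = yy - s
        chest_env = _smooth_rect(xx, ys, chest_x0, chest_x1, chest_y0, chest_y1, edge=2.5)
        tex = cfg.chest.texture_amplitude * (
            np.sin(2 * math.pi * xx / lam) * np.sin(2 * math.pi * ys / (lam * 1.3))
        )
        frame = _blend(frame, chest_env, cfg.chest.temp + tex)

        # head: plateau guarantees max == core + trend before noise
        frame = _blend(frame, head_env, cfg.head.core_temp + head_trend[i])

        boxes = [patient_box, chest_box, head_box]
        for ev, (ecx, ecy, eax, eay) in zip(events, ev_geo):
            if ev.start_s <= t[i] < ev.end_s:
                presence[i] = 1
                # clinician sways sideways while present
                off = 2.0 * math.sin(2 * math.pi * 0.07 * t[i]) + 0.8 * math.sin(
                    2 * math.pi * 0.6 * t[i]
                )
                env = _plateau_ellipse(xx, yy, ecx + off, ecy, eax, eay)
                frame = _blend(frame, env, ev.temp)
                boxes.append(
                    BoundingBox(
                        "clinician",
                        x_min=max(math.floor(ecx + off - eax - 2), 0),
                        y_min=max(math.floor(ecy - eay - 2), 0),
                        x_max=min(math.ceil(ecx + off + eax + 2), w),
                        y_max=min(math.ceil(ecy + eay + 2), h),
                    )
                )

        # ambient drift models camera/room drift: additive on every pixel
        frame = frame + (ambient[i] - cfg.background_temp)
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        track.entries[i] = boxes
        frames.append(ThermalFrame(values=frame, timestamp=float(t[i]), index=i))

    seq = ThermalSequence(frames=frames, fps=cfg.fps, meta={"generator": "thermovitals.synthetic", "seed": cfg.seed})
    truth = SceneTruth(
        boxes=track,
        rr_bpm=cfg.chest.rr_bpm,
        head_trend=head_trend,
        ambient_series=ambient,
        clinician_presence=presence,
        chest_shift=shifts,
    )
    return seq, truth


def generate_detection_fixture(
    truth: SceneTruth | RoiTrack,
    jitter_px: float = 0.0,
    drop_rate: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
) -> RoiTrack:
    """Perturb ground-truth boxes into detector-style predictions.

    Boxes are shifted and resized by Gaussian jitter, dropped with
    probability ``drop_rate`` (emulating detection gaps), and assigned
    confidences that decrease with the applied perturbation.  With zero
    jitter and zero drop rate, predictions equal the truth at
    confidence 1.
    """
    track = truth.boxes if isinstance(truth, SceneTruth) else truth
    if not (0.0 <= drop_rate < 1.0):
        raise ValueError("drop_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = RoiTrack()
    for idx in track.frame_indices():
        kept: list[BoundingBox] = []
        for box in track.boxes(idx):
            if drop_rate > 0 and rng.random() < drop_rate:
                continue
            if jitter_px > 0:
                d = rng.normal(0.0, jitter_px, size=4)
                x0, y0 = box.x_min + d[0], box.y_min + d[1]
                x1, y1 = box.x_max + d[2], box.y_max + d[3]
                if x1 <= x0 + 1:
                    x1 = x0 + 1.0
                if y1 <= y0 + 1:
                    y1 = y0 + 1.0
                shift = float(np.mean(np.abs(d)))
                conf = float(np.clip(0.98 - 0.25 * shift / (jitter_px + 1e-9)
                                     - 0.05 * rng.random(), 0.05, 1.0))
                box = BoundingBox(box.label, x0, y0, x1, y1, confidence=conf)
                if frame_shape is not None:
                    box, _ = box.clip(frame_shape[1], frame_shape[0])
            else:
                box = replace(box, confidence=1.0)
            kept.append(box)
        out.entries[idx] = kept
    return out
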