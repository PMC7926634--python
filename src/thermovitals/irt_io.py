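"""Radiometric thermal-sequence and ROI-label input/output.

Coordinate convention used throughout the package: pixel coordinates are
0-based with the origin at the top-left corner, ``x`` increases to the
right (columns), ``y`` increases downward (rows), and bounding boxes are
half-open intervals ``[x_min, x_max) x [y_min, y_max)``.

Two portable on-disk dialects are supported for radiometric sequences:

``tiff16``
    A multi-page 16-bit TIFF (one page per frame).  Raw counts map to
    degrees Celsius through a linear scale/offset stored as a JSON image
    description, chosen per file as ``scale = (max - min) / 65535`` so the
    quantization step stays at or below the 40 mK sensor sensitivity for
    scene ranges up to ~2.6 K per millikelvin of step.

``csv_stack``
    A directory of one plain-text CSV per frame plus a ``sequence.json``
    sidecar holding fps, timestamps and free-form metadata.  Lossless,
    text-only, and convenient for fixtures.

ROI labels use the darknet text format: one file per frame, one line per
box, ``class_id x_center y_center width height`` with all geometry
normalized to ``[0, 1]``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "CLASS_NAMES",
    "CLASS_IDS",
    "BoundingBox",
    "ThermalFrame",
    "ThermalSequence",
    "RoiTrack",
    "IrtIoError",
    "DialectError",
    "FormatError",
    "LabelParseError",
    "read_sequence",
    "write_sequence",
    "normalize_frame",
    "parse_labels",
    "serialize_labels",
    "read_label_dir",
    "write_label_dir",
    "crop",
]

#: Fixed class ordering shared with the darknet label files.
CLASS_NAMES = ("patient", "chest", "head", "clinician")
CLASS_IDS = {name: i for i, name in enumerate(CLASS_NAMES)}

_MAX_COUNT = 65535


class IrtIoError(Exception):
    """Base error for sequence / label I/O."""


class DialectError(IrtIoError):
    """Unknown dialect or missing dialect-mandated metadata."""


class FormatError(IrtIoError):
    """Structurally broken input (inconsistent shapes, empty sequence...)."""


class LabelParseError(IrtIoError):
    """Malformed darknet label line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in half-open pixel coordinates.

    ``confidence`` is ``None`` for ground-truth boxes and a value in
    ``[0, 1]`` for detector predictions.
    """

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASS_IDS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASS_NAMES}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, width: int, height: int) -> tuple["BoundingBox", bool]:
        """Clamp the box into a ``width x height`` frame.

        Returns the clamped box and a flag that is True when clamping
        actually changed any coordinate (detector jitter at the border).
        """
        x0 = min(max(self.x_min, 0.0), width - 1.0)
        y0 = min(max(self.y_min, 0.0), height - 1.0)
        x1 = max(min(self.x_max, float(width)), x0 + 1.0)
        y1 = max(min(self.y_max, float(height)), y0 + 1.0)
        clipped = (x0, y0, x1, y1) != (self.x_min, self.y_min, self.x_max, self.y_max)
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1), clipped

    def intersects(self, other: "BoundingBox") -> bool:
        return (
            self.x_min < other.x_max
            and other.x_min < self.x_max
            and self.y_min < other.y_max
            and other.y_min < self.y_max
        )


@dataclass
class ThermalFrame:
    """One radiometric frame: a 2-D grid of temperatures in degrees C."""

    values: np.ndarray
    timestamp: float
    index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError(f"frame must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("frame contains non-finite temperatures")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ThermalSequence:
    """An ordered stack of frames with a nominal sampling rate."""

    frames: list[ThermalFrame]
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if not self.frames:
            raise FormatError("sequence must contain at least one frame")
        shape = self.frames[0].shape
        last_t = -math.inf
        for f in self.frames:
            if f.shape != shape:
                raise FormatError(f"inconsistent frame shapes: {f.shape} vs {shape}")
            if f.timestamp < last_t:
                raise FormatError("timestamps must be non-decreasing")
            last_t = f.timestamp

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def as_array(self) -> np.ndarray:
        """Stack all frames into an ``(n, H, W)`` array."""
        return np.stack([f.values for f in self.frames])

    @classmethod
    def from_array(
        cls,
        stack: np.ndarray,
        fps: float,
        timestamps: Sequence[float] | None = None,
        meta: dict | None = None,
    ) -> "ThermalSequence":
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 3:
            raise FormatError(f"expected (n, H, W) stack, got shape {stack.shape}")
        if timestamps is None:
            timestamps = np.arange(stack.shape[0]) / fps
        frames = [
            ThermalFrame(values=stack[i], timestamp=float(timestamps[i]), index=i)
            for i in range(stack.shape[0])
        ]
        return cls(frames=frames, fps=fps, meta=meta or {})


@dataclass
class RoiTrack:
    """Per-frame labeled boxes for one sequence; frames may have no boxes."""

    entries: dict[int, list[BoundingBox]] = field(default_factory=dict)

    def boxes(self, frame_index: int, label: str | None = None) -> list[BoundingBox]:
        out = self.entries.get(frame_index, [])
        if label is None:
            return list(out)
        return [b for b in out if b.label == label]

    def add(self, frame_index: int, box: BoundingBox) -> None:
        self.entries.setdefault(frame_index, []).append(box)

    def n_frames_with(self, label: str) -> int:
        return sum(1 for boxes in self.entries.values() if any(b.label == label for b in boxes))

    def frame_indices(self) -> list[int]:
        return sorted(self.entries)


# ---------------------------------------------------------------------------
# sequence dialects
# ---------------------------------------------------------------------------

def write_sequence(seq: ThermalSequence, path: str | Path, dialect: str = "tiff16") -> Path:
    """Serialize a sequence; see module docstring for the dialects."""
    path = Path(path)
    if dialect == "tiff16":
        return _write_tiff16(seq, path)
    if dialect == "csv_stack":
        return _write_csv_stack(seq, path)
    raise DialectError(f"unknown dialect {dialect!r}")


def read_sequence(path: str | Path, dialect: str = "tiff16") -> ThermalSequence:
    path = Path(path)
    if not path.exists():
        raise IrtIoError(f"no such path: {path}")
    if dialect == "tiff16":
        return _read_tiff16(path)
    if dialect == "csv_stack":
        return _read_csv_stack(path)
    raise DialectError(f"unknown dialect {dialect!r}")


def _write_tiff16(seq: ThermalSequence, path: Path) -> Path:
    stack = seq.as_array()
    lo = float(stack.min())
    hi = float(stack.max())
    scale = (hi - lo) / _MAX_COUNT if hi > lo else 1.0 / _MAX_COUNT
    counts = np.round((stack - lo) / scale).astype(np.uint16)
    desc = json.dumps(
        {
            "thermovitals": 1,
            "scale": scale,
            "offset": lo,
            "fps": seq.fps,
            "timestamps": [f.timestamp for f in seq.frames],
            "meta": seq.meta,
        }
    )
    tifffile.imwrite(path, counts, description=desc, metadata=None)
    return path


def _read_tiff16(path: Path) -> ThermalSequence:
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
        try:
            header = json.loads(desc) if desc else {}
        except json.JSONDecodeError:
            header = {}
        if "scale" not in header or "offset" not in header:
            raise DialectError(f"{path}: tiff16 file lacks scale/offset metadata")
        counts = tif.asarray()
    if counts.ndim == 2:
        counts = counts[None]
    if counts.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2-D pages, got shape {counts.shape}")
    stack = counts.astype(np.float64) * header["scale"] + header["offset"]
    return ThermalSequence.from_array(
        stack,
        fps=float(header.get("fps", 1.0)),
        timestamps=header.get("timestamps"),
        meta=header.get("meta", {}),
    )


_FRAME_RE = re.compile(r"frame_(\d+)\.csv$")


def _write_csv_stack(seq: ThermalSequence, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(seq.frames):
        np.savetxt(path / f"frame_{i:06d}.csv", f.values, delimiter=",", fmt="%.17g")
    sidecar = {
        "fps": seq.fps,
        "timestamps": [f.timestamp for f in seq.frames],
        "meta": seq.meta,
    }
    (path / "sequence.json").write_text(json.dumps(sidecar))
    return path


def _read_csv_stack(path: Path) -> ThermalSequence:
    sidecar_path = path / "sequence.json"
    if not sidecar_path.exists():
        raise DialectError(f"{path}: csv_stack directory lacks sequence.json sidecar")
    sidecar = json.loads(sidecar_path.read_text())
    frame_paths = sorted(p for p in path.iterdir() if _FRAME_RE.search(p.name))
    if not frame_paths:
        raise FormatError(f"{path}: no frame_NNNNNN.csv files found")
    grids = [np.atleast_2d(np.loadtxt(p, delimiter=",", ndmin=2)) for p in frame_paths]
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise FormatError(f"{path}: inconsistent frame shapes {sorted(shapes)}")
    return ThermalSequence.from_array(
        np.stack(grids),
        fps=float(sidecar["fps"]),
        timestamps=sidecar.get("timestamps"),
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# normalization / cropping
# ---------------------------------------------------------------------------

def normalize_frame(frame: ThermalFrame | np.ndarray) -> np.ndarray:
    """Min/max rescale a single frame to ``[0, 1]``.

    Normalization is per frame: scene-temperature changes thus yield
    different per-frame contrasts.  A constant (zero-contrast) frame maps
    to all zeros by convention.
    """
    values = frame.values if isinstance(frame, ThermalFrame) else np.asarray(frame, dtype=np.float64)
    lo = values.min()
    hi = values.max()
    if hi == lo:
        return np.zeros_like(values, dtype=np.float64)
    return (values - lo) / (hi - lo)


def crop(
    frame: ThermalFrame | np.ndarray,
    box: BoundingBox,
    *,
    with_flag: bool = False,
) -> np.ndarray | tuple[np.ndarray, bool]:
    """Extract the half-open sub-grid ``[y_min, y_max) x [x_min, x_max)``.

    Boxes reaching outside the frame are clamped rather than rejected;
    pass ``with_flag=True`` to also receive the ``clipped`` indicator.
    """
    values = frame.values if isinstance(frame, ThermalFrame) else np.asarray(frame)
    h, w = values.shape
    clamped, clipped = box.clip(w, h)
    y0 = int(math.floor(clamped.y_min))
    y1 = int(math.ceil(clamped.y_max))
    x0 = int(math.floor(clamped.x_min))
    x1 = int(math.ceil(clamped.x_max))
    sub = values[y0:y1, x0:x1]
    if sub.size == 0:
        raise FormatError("crop produced an empty grid")
    if with_flag:
        return sub, clipped
    return sub


# ---------------------------------------------------------------------------
# darknet labels
# ---------------------------------------------------------------------------

def parse_labels(path: str | Path, width: int, height: int) -> list[BoundingBox]:
    """Parse one darknet label file into pixel-space boxes.

    Lines are ``class_id x_center y_center w h`` with geometry normalized
    to ``[0, 1]``; class ids follow :data:`CLASS_NAMES` ordering.
    """
    text = Path(path).read_text()
    return parse_label_text(text, width, height)


def parse_label_text(text: str, width: int, height: int) -> list[BoundingBox]:
    boxes: list[BoundingBox] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise LabelParseError(f"expected 5 fields, got {len(parts)}", lineno)
        try:
            class_id = int(parts[0])
            xc, yc, w, h = (float(p) for p in parts[1:5])
        except ValueError as exc:
            raise LabelParseError(str(exc), lineno) from exc
        conf = None
        if len(parts) >= 6:
            conf = float(parts[5])
        if class_id not in range(len(CLASS_NAMES)):
            raise LabelParseError(f"class id {class_id} outside 0..{len(CLASS_NAMES) - 1}", lineno)
        eps = 1e-9
        if not (0 <= xc <= 1 and 0 <= yc <= 1 and 0 < w <= 1 and 0 < h <= 1):
            raise LabelParseError("normalized geometry outside [0, 1]", lineno)
        if xc - w / 2 < -eps or xc + w / 2 > 1 + eps or yc - h / 2 < -eps or yc + h / 2 > 1 + eps:
            raise LabelParseError("box extends outside the unit square", lineno)
        boxes.append(
            BoundingBox(
                label=CLASS_NAMES[class_id],
                x_min=(xc - w / 2) * width,
                y_min=(yc - h / 2) * height,
                x_max=(xc + w / 2) * width,
                y_max=(yc + h / 2) * height,
                confidence=conf,
            )
        )
    return boxes


def serialize_labels(
    boxes: Iterable[BoundingBox],
    width: int,
    height: int,
    path: str | Path | None = None,
    *,
    with_confidence: bool = False,
) -> str:
    """Render boxes back to darknet text (6-decimal fixed point)."""
    lines = []
    for b in boxes:
        xc = (b.x_min + b.x_max) / 2 / width
        yc = (b.y_min + b.y_max) / 2 / height
        w = b.width / width
        h = b.height / height
        fields = f"{CLASS_IDS[b.label]} {xc:.6f} {yc:.6f} {w:.6f} {h:.6f}"
        if with_confidence and b.confidence is not None:
            fields += f" {b.confidence:.6f}"
        lines.append(fields)
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def read_label_dir(path: str | Path, width: int, height: int) -> RoiTrack:
    """Read a directory of ``frame_NNNNNN.txt`` darknet files into a track."""
    path = Path(path)
    track = RoiTrack()
    for p in sorted(path.glob("frame_*.txt")):
        idx = int(p.stem.split("_")[1])
        track.entries[idx] = parse_labels(p, width, height)
    return track


def write_label_dir(
    track: RoiTrack,
    path: str | Path,
    width: int,
    height: int,
    n_frames: int | None = None,
    *,
    with_confidence: bool = False,
) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    indices = track.frame_indices() if n_frames is None else range(n_frames)
    for idx in indices:
        serialize_labels(
            track.boxes(idx),
            width,
            height,
            path / f"frame_{idx:06d}.txt",
            with_confidence=with_confidence,
        )
    return path
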