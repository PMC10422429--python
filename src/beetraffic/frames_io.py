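"""Frame-sequence and annotation I/O.

Videos are processed as ordered sequences of numbered PNG frames
(``frame_%06d.png``, 1-based).  An MP4 file is decoded once into such a
sequence and cached, so all downstream processing is container-independent.
Ground-truth flying-bee annotations use the Darknet/YOLO label dialect: one
text file per frame, one ``class cx cy w h`` line per box with coordinates
normalized to [0, 1] by frame width/height.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Frame",
    "GroundTruthBox",
    "FrameFormatError",
    "load_frames",
    "select_middle_frames",
    "read_labels",
    "write_labels",
    "render_marked_frame",
    "frame_filename",
    "COLOR_ALIGNED",
    "COLOR_UNALIGNED",
    "COLOR_REGION_BOX",
    "COLOR_REGION_CONTOUR",
]

# Marking colors (RGB) for evaluation frames: orange for motion-aligned
# detections, red for motion-unaligned, blue boxes + yellow contour polylines
# for motion regions.
COLOR_ALIGNED = (255, 165, 0)
COLOR_UNALIGNED = (255, 0, 0)
COLOR_REGION_BOX = (0, 0, 255)
COLOR_REGION_CONTOUR = (255, 255, 0)


class FrameFormatError(ValueError):
    """Raised for undecodable frames or malformed annotation lines."""


@dataclass(frozen=True)
class Frame:
    """One video frame: 1-based index plus an H×W×3 (or H×W) uint8 grid."""

    index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"frame index must be >= 1, got {self.index}")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be H×W or H×W×3")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class GroundTruthBox:
    """A labeled bee box in normalized center-size coordinates."""

    frame_index: int
    cx_norm: float
    cy_norm: float
    w_norm: float
    h_norm: float
    class_label: str = "BEE"

    def __post_init__(self) -> None:
        for name in ("cx_norm", "cy_norm", "w_norm", "h_norm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_pixels(self, width_px: int, height_px: int) -> tuple[float, float, float, float]:
        """Return the (x1, y1, x2, y2) pixel rectangle, clamped to the frame."""
        cx = self.cx_norm * width_px
        cy = self.cy_norm * height_px
        w = self.w_norm * width_px
        h = self.h_norm * height_px
        x1 = max(0.0, cx - w / 2)
        y1 = max(0.0, cy - h / 2)
        x2 = min(float(width_px), cx + w / 2)
        y2 = min(float(height_px), cy + h / 2)
        return (x1, y1, x2, y2)


def frame_filename(index: int) -> str:
    return f"frame_{index:06d}.png"


_FRAME_RE = re.compile(r"frame_(\d+)\.png$")


def _cache_mp4(path: Path) -> Path:
    cache = path.with_suffix("")
    cache = cache.parent / (cache.name + "_frames")
    if not cache.is_dir():
        cache.mkdir(parents=True)
        try:
            for i, arr in enumerate(iio.imiter(path), start=1):
                iio.imwrite(cache / frame_filename(i), np.asarray(arr)[..., :3])
        except Exception as exc:  # no decoder backend, corrupt file, ...
            raise FrameFormatError(f"cannot decode video {path}: {exc}") from exc
    return cache


def load_frames(path: str | os.PathLike, first: int, last: int) -> list[Frame]:
    """Load frames ``first..last`` (1-based, inclusive) from a directory of
    numbered PNGs or an MP4 file.

    Returns exactly ``last - first + 1`` frames in ascending index order.
    """
    if first > last:
        raise ValueError(f"empty frame range: first={first} > last={last}")
    if first < 1:
        raise ValueError(f"first frame index must be >= 1, got {first}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such frame source: {p}")
    if p.is_file():
        p = _cache_mp4(p)
    frames: list[Frame] = []
    shape = None
    for i in range(first, last + 1):
        fp = p / frame_filename(i)
        if not fp.exists():
            raise FrameFormatError(f"missing frame {i}: {fp}")
        try:
            arr = np.asarray(iio.imread(fp))
        except Exception as exc:
            raise FrameFormatError(f"undecodable frame {i}: {fp}: {exc}") from exc
        if arr.ndim == 3:
            arr = arr[..., :3]
        if shape is None:
            shape = arr.shape[:2]
        elif arr.shape[:2] != shape:
            raise FrameFormatError(
                f"frame {i} has size {arr.shape[:2]}, expected {shape}")
        frames.append(Frame(index=i, pixels=arr))
    return frames


def select_middle_frames(total_frames: int, n: int) -> tuple[int, int]:
    """1-based inclusive window of the middle ``n`` frames of a video.

    The window starts at ``floor((total - n) / 2) + 1``, e.g. the middle 30
    frames of a 744-frame video are frames 358..387.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n > total_frames:
        raise ValueError(f"n={n} exceeds total_frames={total_frames}")
    first = (total_frames - n) // 2 + 1
    return (first, first + n - 1)


def read_labels(path: str | os.PathLike, frame_index: int = 1) -> list[GroundTruthBox]:
    """Read one Darknet-style label file (may be empty)."""
    boxes: list[GroundTruthBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FrameFormatError(
                    f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:])
            except ValueError as exc:
                raise FrameFormatError(f"{path}:{lineno}: {exc}") from exc
            boxes.append(GroundTruthBox(frame_index=frame_index,
                                        cx_norm=cx, cy_norm=cy,
                                        w_norm=w, h_norm=h,
                                        class_label="BEE" if cls == 0 else str(cls)))
    return boxes


def write_labels(boxes: Iterable[GroundTruthBox], path: str | os.PathLike) -> None:
    """Write boxes in Darknet dialect with 6-decimal coordinates."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"0 {b.cx_norm:.6f} {b.cy_norm:.6f} "
                     f"{b.w_norm:.6f} {b.h_norm:.6f}\n")


def _clamp_box(x1: float, y1: float, x2: float, y2: float,
               w: int, h: int) -> tuple[int, int, int, int]:
    xi1 = int(np.clip(round(x1), 0, w - 1))
    yi1 = int(np.clip(round(y1), 0, h - 1))
    xi2 = int(np.clip(round(x2), 0, w - 1))
    yi2 = int(np.clip(round(y2), 0, h - 1))
    return min(xi1, xi2), min(yi1, yi2), max(xi1, xi2), max(yi1, yi2)


def _draw_rect(img: np.ndarray, box: tuple[float, float, float, float],
               color: tuple[int, int, int]) -> None:
    h, w = img.shape[:2]
    x1, y1, x2, y2 = _clamp_box(*box, w, h)
    img[y1, x1:x2 + 1] = color
    img[y2, x1:x2 + 1] = color
    img[y1:y2 + 1, x1] = color
    img[y1:y2 + 1, x2] = color


def _draw_polyline(img: np.ndarray, points: np.ndarray,
                   color: tuple[int, int, int]) -> None:
    """Draw a closed polyline through (x, y) points, one pixel wide."""
    h, w = img.shape[:2]
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        return
    closed = np.vstack([pts, pts[:1]])
    for (x0, y0), (x1, y1) in zip(closed[:-1], closed[1:]):
        n = int(max(abs(x1 - x0), abs(y1 - y0))) + 1
        xs = np.rint(np.linspace(x0, x1, n)).astype(int)
        ys = np.rint(np.linspace(y0, y1, n)).astype(int)
        keep = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        img[ys[keep], xs[keep]] = color


def render_marked_frame(frame: Frame, aligned: Sequence, unaligned: Sequence,
                        regions: Sequence) -> Frame:
    """Return a marked copy of the frame using the evaluation color scheme.

    Motion-aligned detections get orange rectangles, motion-unaligned red;
    motion regions get blue rectangles plus yellow contour polylines.  The
    input frame is not modified.
    """
    img = frame.pixels.copy()
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    for r in regions:
        _draw_rect(img, (r.x, r.y, r.x + r.w - 1, r.y + r.h - 1), COLOR_REGION_BOX)
        _draw_polyline(img, r.contour, COLOR_REGION_CONTOUR)
    for d in unaligned:
        _draw_rect(img, (d.x1, d.y1, d.x2, d.y2), COLOR_UNALIGNED)
    for d in aligned:
        _draw_rect(img, (d.x1, d.y1, d.x2, d.y2), COLOR_ALIGNED)
    return Frame(index=frame.index, pixels=img)
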