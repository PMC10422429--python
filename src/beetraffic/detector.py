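"""Detector contract and a synthetic oracle detector.

The traffic pipeline is agnostic to the specifics of object inference: any
callable producing per-frame :class:`Detection` boxes with confidence scores
can be plugged in.  Two adapters are provided:

* :class:`OracleDetector` — derives detections from ground-truth boxes with
  configurable miss rate, spurious-box rate, and corner jitter, so every
  downstream stage is testable without trained weights;
* :class:`FileDetector` — replays externally produced detections from a
  whitespace-separated exchange file (``frame_index x1 y1 x2 y2 score``),
  e.g. the output of a trained YOLO model run elsewhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .frames_io import Frame, GroundTruthBox

__all__ = [
    "Detection",
    "OracleDetectorConfig",
    "OracleDetector",
    "FileDetector",
    "filter_by_score",
    "read_detections",
    "write_detections",
    "DEFAULT_SCORE_THRESHOLD",
]

# Reference deployment keeps YOLO boxes with scores of at least 0.7.
DEFAULT_SCORE_THRESHOLD = 0.7


@dataclass(frozen=True)
class Detection:
    """A scored detector box: 0-based pixel corners, x = column, y = row."""

    x1: float
    y1: float
    x2: float
    y2: float
    score: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"degenerate box ({self.x1},{self.y1},{self.x2},{self.y2})")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def cx(self) -> float:
        return self.x1 + (self.x2 - self.x1) / 2

    @property
    def cy(self) -> float:
        # geometric center; see docs/methods.md for the center convention
        return self.y1 + (self.y2 - self.y1) / 2

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class OracleDetectorConfig:
    """Error model of the synthetic detector.

    Each true box independently survives with probability ``1 - miss_rate``;
    surviving corners are jittered with Gaussian noise (σ = ``jitter_px``);
    scores are drawn uniformly from ``score_range``; ``Poisson(spurious_rate)``
    spurious boxes per frame are placed uniformly at random.
    """

    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    jitter_px: float = 0.0
    score_range: tuple[float, float] = (0.7, 1.0)
    spurious_size_px: tuple[float, float] = (10.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0, 1]")
        if self.spurious_rate < 0 or self.jitter_px < 0:
            raise ValueError("rates must be non-negative")


class OracleDetector:
    """Synthetic detector that corrupts ground truth per its error model.

    Deterministic under a fixed seed: each frame uses an RNG stream derived
    from ``(seed, frame_index)``, so results do not depend on processing
    order.
    """

    def __init__(self, config: OracleDetectorConfig = OracleDetectorConfig()):
        self.config = config

    def __call__(self, frame: Frame,
                 ground_truth: Sequence[GroundTruthBox]) -> list[Detection]:
        return self.detect(frame, ground_truth)

    def detect(self, frame: Frame,
               ground_truth: Sequence[GroundTruthBox]) -> list[Detection]:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, frame.index])
        w, h = frame.width_px, frame.height_px
        out: list[Detection] = []
        for gt in ground_truth:
            if rng.random() < cfg.miss_rate:
                continue
            x1, y1, x2, y2 = gt.to_pixels(w, h)
            if cfg.jitter_px > 0:
                jx1, jy1, jx2, jy2 = rng.normal(0.0, cfg.jitter_px, size=4)
                x1, y1, x2, y2 = x1 + jx1, y1 + jy1, x2 + jx2, y2 + jy2
                x1, x2 = min(x1, x2), max(x1, x2)
                y1, y2 = min(y1, y2), max(y1, y2)
                if x2 - x1 < 1:
                    x2 = x1 + 1
                if y2 - y1 < 1:
                    y2 = y1 + 1
            score = rng.uniform(*cfg.score_range)
            out.append(Detection(x1, y1, x2, y2, score))
        n_spurious = rng.poisson(cfg.spurious_rate) if cfg.spurious_rate > 0 else 0
        for _ in range(n_spurious):
            bw = rng.uniform(*cfg.spurious_size_px)
            bh = rng.uniform(*cfg.spurious_size_px)
            x1 = rng.uniform(0, max(w - bw, 1))
            y1 = rng.uniform(0, max(h - bh, 1))
            score = rng.uniform(*cfg.score_range)
            out.append(Detection(x1, y1, x1 + bw, y1 + bh, score))
        return out


class FileDetector:
    """Replays detections from an exchange file, keyed by frame index."""

    def __init__(self, path: str | os.PathLike):
        self._by_frame: dict[int, list[Detection]] = {}
        for idx, det in read_detections(path):
            self._by_frame.setdefault(idx, []).append(det)

    def __call__(self, frame: Frame, ground_truth=None) -> list[Detection]:
        return list(self._by_frame.get(frame.index, []))


def filter_by_score(detections: Iterable[Detection],
                    threshold: float = DEFAULT_SCORE_THRESHOLD) -> list[Detection]:
    """Keep detections with ``score >= threshold`` (order preserved)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return [d for d in detections if d.score >= threshold]


def read_detections(path: str | os.PathLike) -> list[tuple[int, Detection]]:
    """Read ``frame_index x1 y1 x2 y2 score`` lines."""
    out: list[tuple[int, Detection]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            idx = int(parts[0])
            x1, y1, x2, y2, score = (float(v) for v in parts[1:])
            out.append((idx, Detection(x1, y1, x2, y2, score)))
    return out


def write_detections(items: Iterable[tuple[int, Detection]],
                     path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for idx, d in items:
            fh.write(f"{idx} {d.x1:.3f} {d.y1:.3f} {d.x2:.3f} {d.y2:.3f} "
                     f"{d.score:.4f}\n")
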