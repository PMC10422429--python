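"""Object-motion alignment and the sequential per-frame pipeline.

A score-filtered detection is *motion-aligned* when at least one motion
region's center lies within a Euclidean radius (default 50 px) of the
detection's box center; otherwise it is *motion-unaligned*.  Radius queries
run against a k-d tree over region centers.  The video-level omnidirectional
traffic measurement is the total count of motion-aligned detections across
processed frames — the same bee in flight can contribute once per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detector import Detection, filter_by_score, DEFAULT_SCORE_THRESHOLD
from .frames_io import Frame, GroundTruthBox
from .motion_detect import MotionParams, MotionRegion, detect_motion_regions

__all__ = [
    "AlignmentParams",
    "AlignedDetection",
    "FrameAlignment",
    "MotionIndex",
    "build_motion_index",
    "align",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Euclidean radius for object-motion alignment (default 50 px)."""

    max_distance_px: float = 50.0

    def __post_init__(self) -> None:
        if self.max_distance_px <= 0:
            raise ValueError("max_distance_px must be positive")


@dataclass(frozen=True)
class AlignedDetection:
    """A motion-aligned detection with its matched region and distance."""

    detection: Detection
    region_index: int
    distance: float

    # convenience pass-throughs so marked-frame rendering can treat aligned
    # and plain detections uniformly
    @property
    def x1(self): return self.detection.x1
    @property
    def y1(self): return self.detection.y1
    @property
    def x2(self): return self.detection.x2
    @property
    def y2(self): return self.detection.y2
    @property
    def cx(self): return self.detection.cx
    @property
    def cy(self): return self.detection.cy
    @property
    def score(self): return self.detection.score


@dataclass
class FrameAlignment:
    """Per-frame output: motion regions, aligned and unaligned detections."""

    frame_index: int
    regions: list[MotionRegion]
    aligned: list[AlignedDetection]
    unaligned: list[Detection]


class MotionIndex:
    """k-d tree over motion-region centers supporting radius queries."""

    def __init__(self, regions: Sequence[MotionRegion]):
        self.regions = list(regions)
        self._centers = np.array([r.center for r in self.regions], dtype=float)
        self._tree = cKDTree(self._centers) if len(self.regions) else None

    def query_radius(self, point: tuple[float, float], radius: float) -> list[int]:
        """Indices of all regions whose center is within ``radius`` (<=)."""
        if self._tree is None:
            return []
        return sorted(self._tree.query_ball_point(point, radius))

    def nearest_within(self, point: tuple[float, float],
                       radius: float) -> Optional[tuple[int, float]]:
        """Nearest region index and distance within ``radius``, or None.

        Distance ties are broken by the lowest region index.
        """
        hits = self.query_radius(point, radius)
        if not hits:
            return None
        pt = np.asarray(point, dtype=float)
        dists = np.linalg.norm(self._centers[hits] - pt, axis=1)
        best = int(np.argmin(dists))  # argmin takes the first = lowest index
        return hits[best], float(dists[best])


def build_motion_index(regions: Sequence[MotionRegion]) -> MotionIndex:
    return MotionIndex(regions)


def align(detections: Sequence[Detection], index: MotionIndex,
          params: AlignmentParams = AlignmentParams()) -> FrameAlignment:
    """Partition score-filtered detections by radius queries on box centers.

    A distance exactly equal to ``max_distance_px`` counts as aligned.
    """
    aligned: list[AlignedDetection] = []
    unaligned: list[Detection] = []
    for det in detections:
        hit = index.nearest_within((det.cx, det.cy), params.max_distance_px)
        if hit is None:
            unaligned.append(det)
        else:
            aligned.append(AlignedDetection(det, region_index=hit[0],
                                            distance=hit[1]))
    return FrameAlignment(frame_index=-1, regions=index.regions,
                          aligned=aligned, unaligned=unaligned)


@dataclass
class PipelineResult:
    """Per-frame alignments plus the video-level traffic count."""

    frames: list[FrameAlignment]
    traffic_count: int


def run_pipeline(frames: Sequence[Frame],
                 detector: Callable[..., list[Detection]],
                 motion_params: MotionParams = MotionParams(),
                 align_params: AlignmentParams = AlignmentParams(),
                 score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                 ground_truth: Optional[dict[int, list[GroundTruthBox]]] = None,
                 ) -> PipelineResult:
    """Sequentially run inference, motion detection, and alignment per frame.

    ``detector`` is called as ``detector(frame, gt_boxes)`` where
    ``gt_boxes`` comes from ``ground_truth`` (oracle adapters use it; file
    adapters ignore it).  The first frame has no preceding frame and hence no
    motion regions; all of its detections are unaligned.  The traffic count
    is the total number of motion-aligned detections.
    """
    if len(frames) < 2:
        raise ValueError("pipeline requires at least 2 frames")
    results: list[FrameAlignment] = []
    count = 0
    prev = None
    for frame in frames:
        gt = (ground_truth or {}).get(frame.index, [])
        detections = filter_by_score(detector(frame, gt), score_threshold)
        if prev is None:
            regions: list[MotionRegion] = []
        else:
            regions = detect_motion_regions(prev, frame, motion_params)
        fa = align(detections, build_motion_index(regions), align_params)
        fa.frame_index = frame.index
        results.append(fa)
        count += len(fa.aligned)
        prev = frame
    return PipelineResult(frames=results, traffic_count=count)
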