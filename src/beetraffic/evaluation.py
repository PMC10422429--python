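"""Seven-category accuracy taxonomy and confusion-count metrics.

Each ground-truth-vs-pipeline event in a frame is labeled with one of seven
joint categories of detection correctness and motion status:

====================  ===========================================  =======
category              meaning                                      counted
====================  ===========================================  =======
``BTP_BFLMTP``        bee detected, flying, motion confirms        TP
``BTP_BCRMTP``        bee detected, crawling/wing motion confirms  TP
``BTP_BMTN``          bee detected, stationary, no motion          TP
``BTP_BMFN``          bee detected, moving, but motion missed      TP
``BFN_BFLMTP``        flying bee missed by detector, motion saw    FN
``BFN_BFLMFN``        flying bee missed by detector and motion     FN
``BFP``               detection with no underlying bee             FP
====================  ===========================================  =======

Two criteria decide whether a motion region "confirms" an event:
C1 — the region center lies within the alignment radius of the event center;
C2 — the region rectangle has a strictly positive intersection area with the
event box.

The four summary metrics are computed exactly as reported in the study this
package reproduces, whose precision/recall denominators are swapped relative
to standard usage (precision = TP/(TP+FN), recall = TP/(TP+FP)); field names
carry the ``_as_printed`` suffix so consumers are not misled.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._util import rect_intersection_area, rect_iou, round_half_away
from .alignment import AlignmentParams
from .detector import Detection
from .motion_detect import MotionRegion

__all__ = [
    "EvalCategory",
    "MotionState",
    "GroundTruthEvent",
    "ConfusionCounts",
    "MetricSet",
    "classify_event",
    "match_detections_to_truth",
    "evaluate_frame",
    "tally",
    "compute_metrics",
    "pool_counts",
    "mean_metrics",
]


class MotionState(enum.Enum):
    FLYING = "FLYING"
    CRAWLING = "CRAWLING"
    STATIONARY = "STATIONARY"


class EvalCategory(enum.Enum):
    BTP_BFLMTP = "BTP_BFLMTP"
    BTP_BCRMTP = "BTP_BCRMTP"
    BTP_BMTN = "BTP_BMTN"
    BTP_BMFN = "BTP_BMFN"
    BFN_BFLMTP = "BFN_BFLMTP"
    BFN_BFLMFN = "BFN_BFLMFN"
    BFP = "BFP"


TP_CATEGORIES = frozenset({EvalCategory.BTP_BFLMTP, EvalCategory.BTP_BCRMTP,
                           EvalCategory.BTP_BMTN, EvalCategory.BTP_BMFN})
FN_CATEGORIES = frozenset({EvalCategory.BFN_BFLMTP, EvalCategory.BFN_BFLMFN})


@dataclass(frozen=True)
class GroundTruthEvent:
    """One annotated bee in a frame, with its known motion state."""

    frame_index: int
    box: tuple[float, float, float, float]  # (x1, y1, x2, y2) pixels
    motion_state: MotionState

    @property
    def center(self) -> tuple[float, float]:
        x1, y1, x2, y2 = self.box
        return (x1 + (x2 - x1) / 2, y1 + (y2 - y1) / 2)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    FP: int
    NF: int = 0  # number of frames
    NV: int = 0  # number of videos

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    """The four as-printed metrics (see module docstring for the swap)."""

    precision_as_printed: float  # TP / (TP + FN)
    recall_as_printed: float     # TP / (TP + FP)
    f1_as_printed: float
    iou_as_printed: float        # TP / (TP + FP + FN)

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        """Metrics rounded half-away-from-zero for table reproduction."""
        return MetricSet(*(round_half_away(v, ndigits) for v in (
            self.precision_as_printed, self.recall_as_printed,
            self.f1_as_printed, self.iou_as_printed)))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.precision_as_printed, self.recall_as_printed,
                self.f1_as_printed, self.iou_as_printed)


def _motion_confirms(region: Optional[MotionRegion],
                     center: tuple[float, float],
                     box: tuple[float, float, float, float],
                     params: AlignmentParams) -> bool:
    """C1 ∧ C2 for one candidate motion region against an event box."""
    if region is None:
        return False
    rcx, rcy = region.center
    dist = float(np.hypot(rcx - center[0], rcy - center[1]))
    if dist > params.max_distance_px:  # C1
        return False
    return rect_intersection_area(region.rect, box) > 0  # C2


def classify_event(gt: Optional[GroundTruthEvent],
                   detection_match: Optional[Detection],
                   motion_match: Optional[MotionRegion],
                   params: AlignmentParams = AlignmentParams()
                   ) -> Optional[EvalCategory]:
    """Label one event with its category (decision table in module docstring).

    ``motion_match`` is the candidate motion region for the event (or None);
    C1 ∧ C2 are re-checked here against the detection box when present,
    otherwise against the ground-truth box.  Returns None for the one
    configuration outside the taxonomy: an undetected non-flying bee (the FN
    categories cover flying bees only).
    """
    if gt is None and detection_match is None:
        raise ValueError("at least one of gt / detection_match is required")
    if gt is None:
        return EvalCategory.BFP
    if detection_match is not None:
        center = (detection_match.cx, detection_match.cy)
        box = detection_match.box
    else:
        center = gt.center
        box = gt.box
    confirmed = _motion_confirms(motion_match, center, box, params)
    if detection_match is not None:
        if confirmed:
            return (EvalCategory.BTP_BFLMTP
                    if gt.motion_state is MotionState.FLYING
                    else EvalCategory.BTP_BCRMTP)
        return (EvalCategory.BTP_BMTN
                if gt.motion_state is MotionState.STATIONARY
                else EvalCategory.BTP_BMFN)
    if gt.motion_state is not MotionState.FLYING:
        return None
    return EvalCategory.BFN_BFLMTP if confirmed else EvalCategory.BFN_BFLMFN


def match_detections_to_truth(detections: Sequence[Detection],
                              ground_truth: Sequence[GroundTruthEvent]
                              ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching by descending box IoU.

    Pairs with IoU > 0 are accepted; ties are broken by (gt index, detection
    index).  Returns (matched (gt_idx, det_idx) pairs, unmatched gt indices,
    unmatched detection indices).
    """
    candidates = []
    for gi, gt in enumerate(ground_truth):
        for di, det in enumerate(detections):
            iou = rect_iou(gt.box, det.box)
            if iou > 0:
                candidates.append((-iou, gi, di))
    candidates.sort()
    used_gt: set[int] = set()
    used_det: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, gi, di in candidates:
        if gi in used_gt or di in used_det:
            continue
        pairs.append((gi, di))
        used_gt.add(gi)
        used_det.add(di)
    unmatched_gt = [i for i in range(len(ground_truth)) if i not in used_gt]
    unmatched_det = [i for i in range(len(detections)) if i not in used_det]
    return pairs, unmatched_gt, unmatched_det


def _best_confirming_region(regions: Sequence[MotionRegion],
                            center: tuple[float, float],
                            box: tuple[float, float, float, float],
                            params: AlignmentParams) -> Optional[MotionRegion]:
    best = None
    best_dist = np.inf
    for r in regions:
        if _motion_confirms(r, center, box, params):
            d = float(np.hypot(r.center[0] - center[0], r.center[1] - center[1]))
            if d < best_dist:
                best, best_dist = r, d
    return best


def evaluate_frame(ground_truth: Sequence[GroundTruthEvent],
                   detections: Sequence[Detection],
                   regions: Sequence[MotionRegion],
                   params: AlignmentParams = AlignmentParams(),
                   ignore_boxes: Sequence[tuple[float, float, float, float]] = ()
                   ) -> list[EvalCategory]:
    """Classify every event in one frame.

    Detections overlapping an ``ignore_boxes`` rectangle (e.g. partially
    occluded, deliberately unlabeled bees) are excluded from all tallies.
    """
    detections = [d for d in detections
                  if not any(rect_intersection_area(d.box, ib) > 0
                             for ib in ignore_boxes)]
    pairs, unmatched_gt, unmatched_det = match_detections_to_truth(
        detections, ground_truth)
    cats: list[EvalCategory] = []
    for gi, di in pairs:
        det = detections[di]
        region = _best_confirming_region(
            regions, (det.cx, det.cy), det.box, params)
        cat = classify_event(ground_truth[gi], det, region, params)
        if cat is not None:
            cats.append(cat)
    for gi in unmatched_gt:
        gt = ground_truth[gi]
        region = _best_confirming_region(regions, gt.center, gt.box, params)
        cat = classify_event(gt, None, region, params)
        if cat is not None:
            cats.append(cat)
    for _di in unmatched_det:
        cats.append(EvalCategory.BFP)
    return cats


def tally(categories: Sequence[EvalCategory], nf: int = 0, nv: int = 0
          ) -> ConfusionCounts:
    """Aggregate category labels into TP/FN/FP counts."""
    tp = sum(1 for c in categories if c in TP_CATEGORIES)
    fn = sum(1 for c in categories if c in FN_CATEGORIES)
    fp = sum(1 for c in categories if c is EvalCategory.BFP)
    return ConfusionCounts(TP=tp, FN=fn, FP=fp, NF=nf, NV=nv)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The four as-printed metrics from confusion counts.

    precision = TP/(TP+FN), recall = TP/(TP+FP) (denominators swapped
    relative to standard usage — implemented verbatim as reported),
    f1 = harmonic mean, iou = TP/(TP+FP+FN).  Undefined metrics (zero
    denominator) are reported as NaN with a warning.
    """
    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          RuntimeWarning, stacklevel=3)
            return float("nan")
        return num / den

    precision = _ratio(c.TP, c.TP + c.FN, "precision")
    recall = _ratio(c.TP, c.TP + c.FP, "recall")
    if precision != precision or recall != recall or precision + recall == 0:
        f1 = float("nan") if (precision != precision or recall != recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    iou = _ratio(c.TP, c.TP + c.FP + c.FN, "iou")
    return MetricSet(precision, recall, f1, iou)


def pool_counts(per_stratum: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Elementwise sums of TP/FN/FP (and NF/NV) across strata.

    Pooling, not averaging, reproduces the reported TOTAL rows: e.g. pooled
    precision 1210/(1210+3158) ≈ 0.28 rather than mean(0.39, 0.24) = 0.315.
    """
    if not per_stratum:
        raise ValueError("need at least one stratum")
    return ConfusionCounts(TP=sum(c.TP for c in per_stratum),
                           FN=sum(c.FN for c in per_stratum),
                           FP=sum(c.FP for c in per_stratum),
                           NF=sum(c.NF for c in per_stratum),
                           NV=sum(c.NV for c in per_stratum))


def mean_metrics(per_stratum: Sequence[ConfusionCounts]) -> MetricSet:
    """Secondary aggregate: unweighted mean of per-stratum metrics."""
    sets = [compute_metrics(c).as_tuple() for c in per_stratum]
    arr = np.array(sets, dtype=float)
    return MetricSet(*(float(v) for v in arr.mean(axis=0)))
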