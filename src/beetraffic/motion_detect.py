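"""Inter-frame motion-region detection.

The operator chain works on two consecutive frames: grayscale both, Gaussian
blur with a small odd kernel, pixelwise absolute difference, grey dilation to
make the differences more pronounced, binary thresholding, external-boundary
contour tracing with simplified chain approximation, and a polygon-area filter
that drops contours too small to contain one flying bee.  Each survivor is
reported as a motion region: its contour, polygon area, and smallest enclosing
axis-aligned rectangle ``(x, y, w, h)`` with 0-based top-left pixel origin.

Defaults follow the reference deployment on 1080-row video: 5×5 blur and
dilation kernels, difference threshold 20, minimum contour area 1000 px.  On
smaller frames the area threshold should be rescaled proportionally to the
frame area (see :func:`scaled_min_area`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .frames_io import Frame

__all__ = [
    "MotionParams",
    "MotionRegion",
    "detect_motion_regions",
    "region_center",
    "motion_mask",
    "find_motion_contours",
    "trace_boundary",
    "simplify_contour",
    "polygon_area",
    "scaled_min_area",
    "GRAY_WEIGHTS",
]

# ITU-R BT.601 luma weights for RGB grayscaling.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class MotionParams:
    """Tunable parameters of the motion-detection chain.

    ``sigma`` defaults to the kernel-size-derived value
    ``0.3·((k−1)/2 − 1) + 0.8``, the de-facto convention for kernel-only
    Gaussian blurs.
    """

    blur_kernel: int = 5
    dilate_kernel: int = 5
    diff_threshold: int = 20
    min_contour_area: float = 1000.0
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("blur_kernel", "dilate_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {k}")
        if not (0 <= self.diff_threshold <= 255):
            raise ValueError("diff_threshold must be in [0, 255]")
        if self.min_contour_area <= 0:
            raise ValueError("min_contour_area must be positive")

    @property
    def effective_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        k = self.blur_kernel
        return 0.3 * ((k - 1) / 2 - 1) + 0.8


@dataclass(frozen=True)
class MotionRegion:
    """A thresholded-difference contour with its enclosing rectangle."""

    x: int
    y: int
    w: int
    h: int
    contour: np.ndarray  # N×2 array of (x, y) boundary points, pixel centers
    area: float          # shoelace polygon area of the contour

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("region must have positive width and height")

    @property
    def center(self) -> tuple[float, float]:
        return region_center(self)

    @property
    def rect(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) corners of the enclosing rectangle."""
        return (float(self.x), float(self.y),
                float(self.x + self.w), float(self.y + self.h))


def region_center(region: MotionRegion) -> tuple[float, float]:
    """Center ``(x + w/2, y + h/2)`` of the enclosing rectangle, as floats."""
    return (region.x + region.w / 2, region.y + region.h / 2)


def scaled_min_area(frame_shape: tuple[int, int],
                    reference_shape: tuple[int, int] = (1080, 1920),
                    reference_area: float = 1000.0) -> float:
    """Rescale the minimum contour area proportionally to frame area."""
    h, w = frame_shape
    rh, rw = reference_shape
    return reference_area * (h * w) / (rh * rw)


def _grayscale(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 2:
        return pixels.astype(np.float64)
    r, g, b = GRAY_WEIGHTS
    return (pixels[..., 0] * r + pixels[..., 1] * g + pixels[..., 2] * b)


def _gaussian_kernel_1d(k: int, sigma: float) -> np.ndarray:
    half = (k - 1) / 2
    xs = np.arange(k) - half
    g = np.exp(-(xs ** 2) / (2.0 * sigma ** 2))
    return g / g.sum()


def _blur(gray: np.ndarray, k: int, sigma: float) -> np.ndarray:
    kern = _gaussian_kernel_1d(k, sigma)
    out = ndimage.correlate1d(gray, kern, axis=0, mode="mirror")
    out = ndimage.correlate1d(out, kern, axis=1, mode="mirror")
    return out


def motion_mask(frame_a: Frame, frame_b: Frame,
                params: MotionParams = MotionParams()) -> np.ndarray:
    """Binary foreground mask of the blur/diff/dilate/threshold stages."""
    if frame_a.pixels.shape[:2] != frame_b.pixels.shape[:2]:
        raise ValueError(
            f"frame size mismatch: {frame_a.pixels.shape[:2]} vs "
            f"{frame_b.pixels.shape[:2]}")
    sigma = params.effective_sigma
    ga = _blur(_grayscale(frame_a.pixels), params.blur_kernel, sigma)
    gb = _blur(_grayscale(frame_b.pixels), params.blur_kernel, sigma)
    diff = np.abs(ga - gb)
    dilated = ndimage.grey_dilation(
        diff, size=(params.dilate_kernel, params.dilate_kernel), mode="nearest")
    return dilated > params.diff_threshold


_N8 = np.ones((3, 3), dtype=int)  # 8-connectivity for components

# Moore neighborhood in clockwise order (dr, dc), starting west.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def trace_boundary(component: np.ndarray) -> np.ndarray:
    """Trace the external boundary of one 8-connected component.

    ``component`` is a boolean mask containing a single connected component.
    Returns the closed boundary as an N×2 array of (x, y) pixel centers
    (Moore-neighbor tracing with Jacob's stopping criterion).  A single-pixel
    component yields a length-1 contour.
    """
    rows, cols = np.nonzero(component)
    if len(rows) == 0:
        return np.empty((0, 2), dtype=float)
    order = np.lexsort((cols, rows))  # uppermost, then leftmost
    start = (int(rows[order[0]]), int(cols[order[0]]))
    if len(rows) == 1:
        return np.array([[start[1], start[0]]], dtype=float)

    h, w = component.shape

    def filled(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < h and 0 <= c < w and bool(component[r, c])

    boundary: list[tuple[int, int]] = [start]
    backtrack = (start[0], start[1] - 1)
    cur = start
    first_state = None
    while True:
        off = (backtrack[0] - cur[0], backtrack[1] - cur[1])
        base = _MOORE_INDEX[off]
        nxt = None
        for i in range(1, 9):
            cand_off = _MOORE[(base + i) % 8]
            cand = (cur[0] + cand_off[0], cur[1] + cand_off[1])
            if filled(cand):
                nxt = cand
                # backtrack = the last background pixel scanned before cand
                prev_off = _MOORE[(base + i - 1) % 8]
                backtrack = (cur[0] + prev_off[0], cur[1] + prev_off[1])
                break
        if nxt is None:  # isolated pixel (cannot happen for len > 1)
            break
        state = (nxt, backtrack)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        cur = nxt
        boundary.append(cur)
    # drop the duplicated closing point if present
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return np.array([[c, r] for r, c in boundary], dtype=float)


def simplify_contour(contour: np.ndarray) -> np.ndarray:
    """Collapse collinear runs to their endpoints (simple chain approximation).

    Keeps every point where the step direction changes, treating the contour
    as closed.  Preserves the shoelace polygon area exactly.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        return pts
    keep = []
    n = len(pts)
    for i in range(n):
        prev_dir = pts[i] - pts[(i - 1) % n]
        next_dir = pts[(i + 1) % n] - pts[i]
        # cross product and parallelism test: keep corners
        if prev_dir[0] * next_dir[1] - prev_dir[1] * next_dir[0] != 0 or \
           prev_dir[0] * next_dir[0] + prev_dir[1] * next_dir[1] < 0:
            keep.append(i)
    if not keep:  # degenerate (all collinear): keep endpoints
        return pts[[0, len(pts) // 2]]
    return pts[keep]


def polygon_area(contour: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon through pixel centers."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        return 0.0
    x = pts[:, 0]
    y = pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def find_motion_contours(mask: np.ndarray, min_contour_area: float) -> list[MotionRegion]:
    """Extract filtered motion regions from a binary foreground mask.

    External boundaries of 8-connected components are traced and simplified;
    contours with polygon area below ``min_contour_area`` are discarded.
    Regions are ordered by (y, x) of the enclosing rectangle's top-left
    corner, then by area descending.
    """
    labeled, n = ndimage.label(mask, structure=_N8)
    regions: list[MotionRegion] = []
    for sl, lab in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        comp = labeled[sl] == lab
        contour = trace_boundary(comp)
        # shift contour from slice-local to frame coordinates
        contour = contour + np.array([sl[1].start, sl[0].start], dtype=float)
        contour = simplify_contour(contour)
        area = polygon_area(contour)
        if area < min_contour_area:
            continue
        rows, cols = np.nonzero(comp)
        x = int(cols.min()) + sl[1].start
        y = int(rows.min()) + sl[0].start
        w = int(cols.max() - cols.min()) + 1
        h = int(rows.max() - rows.min()) + 1
        regions.append(MotionRegion(x=x, y=y, w=w, h=h, contour=contour,
                                    area=area))
    regions.sort(key=lambda r: (r.y, r.x, -r.area))
    return regions


def detect_motion_regions(frame_a: Frame, frame_b: Frame,
                          params: MotionParams = MotionParams()) -> list[MotionRegion]:
    """Run the full chain on a consecutive frame pair.

    Regions are attributed to ``frame_b`` (the later frame); the first frame
    of a video therefore has no motion regions.
    """
    mask = motion_mask(frame_a, frame_b, params)
    return find_motion_contours(mask, params.min_contour_area)
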