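"""Independent brute-force reference implementations used as test oracles.

Deliberately written with a different mechanism than the library (padded
numpy shifts and flood fill instead of scipy.ndimage; exhaustive assignment
instead of greedy matching) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def luma(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 2:
        return pixels.astype(float)
    return (0.299 * pixels[..., 0] + 0.587 * pixels[..., 1]
            + 0.114 * pixels[..., 2])


def blur_shift(gray: np.ndarray, k: int, sigma: float) -> np.ndarray:
    half = (k - 1) // 2
    xs = np.arange(k) - half
    g = np.exp(-(xs ** 2) / (2 * sigma ** 2))
    g = g / g.sum()
    kernel = np.outer(g, g)
    padded = np.pad(gray.astype(float), half, mode="reflect")
    h, w = gray.shape
    out = np.zeros((h, w))
    for dr in range(k):
        for dc in range(k):
            out += kernel[dr, dc] * padded[dr:dr + h, dc:dc + w]
    return out


def dilate_shift(img: np.ndarray, k: int) -> np.ndarray:
    half = (k - 1) // 2
    padded = np.pad(img, half, mode="edge")
    h, w = img.shape
    stack = [padded[dr:dr + h, dc:dc + w]
             for dr in range(k) for dc in range(k)]
    return np.max(stack, axis=0)


def motion_mask_bruteforce(pixels_a: np.ndarray, pixels_b: np.ndarray,
                           blur_kernel: int, dilate_kernel: int,
                           diff_threshold: float, sigma: float) -> np.ndarray:
    ba = blur_shift(luma(pixels_a), blur_kernel, sigma)
    bb = blur_shift(luma(pixels_b), blur_kernel, sigma)
    diff = np.abs(ba - bb)
    return dilate_shift(diff, dilate_kernel) > diff_threshold


def components_floodfill(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected foreground components via BFS flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = np.zeros_like(mask, dtype=bool)
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp[r, c] = True
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


def radius_hits_bruteforce(centers: np.ndarray, query: tuple[float, float],
                           radius: float) -> list[int]:
    out = []
    for i, (cx, cy) in enumerate(centers):
        if (cx - query[0]) ** 2 + (cy - query[1]) ** 2 <= radius ** 2:
            out.append(i)
    return out


def iou(a, b) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    if w <= 0 or h <= 0:
        return 0.0
    inter = w * h
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def best_matching_exhaustive(gt_boxes, det_boxes):
    """Maximum-cardinality, then maximum-total-IoU one-to-one assignment
    over all injective mappings with positive-IoU pairs (instances <= 8)."""
    n_gt, n_det = len(gt_boxes), len(det_boxes)
    best = (-1, -1.0, [])  # (count, total iou, pairs)
    det_indices = list(range(n_det))
    for k in range(min(n_gt, n_det), -1, -1):
        for gt_subset in itertools.combinations(range(n_gt), k):
            for det_perm in itertools.permutations(det_indices, k):
                ious = [iou(gt_boxes[g], det_boxes[d])
                        for g, d in zip(gt_subset, det_perm)]
                if any(v <= 0 for v in ious):
                    continue
                cand = (k, sum(ious), list(zip(gt_subset, det_perm)))
                if (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
        if best[0] == k and best[0] >= 0:
            break
    return best[2]


def middle_window_enumeration(total: int, n: int) -> tuple[int, int]:
    """Pick the length-n window of 1..total whose first index equals
    floor((total-n)/2)+1 by enumerating all candidate windows."""
    windows = [(first, first + n - 1) for first in range(1, total - n + 2)]
    target_first = (total - n) // 2 + 1
    for w in windows:
        if w[0] == target_first:
            return w
    raise AssertionError("no window found")
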