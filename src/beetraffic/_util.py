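"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used in the reported tables).

    Python's builtin ``round`` uses banker's rounding, which would turn e.g.
    0.125 into 0.12 instead of 0.13.
    """
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rect_intersection_area(a: tuple[float, float, float, float],
                           b: tuple[float, float, float, float]) -> float:
    """Intersection area of two (x1, y1, x2, y2) axis-aligned rectangles."""
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    if w <= 0 or h <= 0:
        return 0.0
    return float(w * h)


def rect_iou(a: tuple[float, float, float, float],
             b: tuple[float, float, float, float]) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) rectangles."""
    inter = rect_intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)
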