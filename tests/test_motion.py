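import numpy as np
import pytest
from hypothesis import given, strategies as st

from beetraffic.frames_io import Frame
from beetraffic.motion_detect import (MotionParams, MotionRegion,
                                      detect_motion_regions,
                                      find_motion_contours, motion_mask,
                                      polygon_area, region_center,
                                      scaled_min_area, simplify_contour,
                                      trace_boundary)

from .oracles import motion_mask_bruteforce


def _gray_frame(index, arr):
    return Frame(index, arr.astype(np.uint8))


class TestOperatorChain:
    def test_identical_frames_yield_nothing(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (64, 64), dtype=np.uint8)
        f = _gray_frame(1, img)
        assert detect_motion_regions(f, _gray_frame(2, img)) == []

    def test_bright_disk_yields_one_containing_region(self):
        h = w = 200
        a = _gray_frame(1, np.zeros((h, w)))
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.where((yy - 100) ** 2 + (xx - 100) ** 2 <= 20 ** 2, 255, 0)
        (region,) = detect_motion_regions(a, _gray_frame(2, img))
        # enclosing rectangle contains the rendered disk
        assert region.x <= 80 and region.y <= 80
        assert region.x + region.w >= 121 and region.y + region.h >= 121
        assert region.area >= 1000

    def test_small_square_rejected_by_area_filter(self):
        a = _gray_frame(1, np.zeros((200, 200)))
        img = np.zeros((200, 200))
        img[90:110, 90:110] = 255  # 20x20, far below 1000 px
        assert detect_motion_regions(a, _gray_frame(2, img)) == []

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            motion_mask(_gray_frame(1, np.zeros((10, 10))),
                        _gray_frame(2, np.zeros((12, 10))))

    def test_mask_equals_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        params = MotionParams()
        for _ in range(10):
            h, w = rng.integers(16, 65, 2)
            pa = rng.integers(0, 256, (h, w, 3)).astype(np.uint8)
            pb = pa.copy()
            r0, c0 = rng.integers(0, h - 8), rng.integers(0, w - 8)
            pb[r0:r0 + 8, c0:c0 + 8] = rng.integers(0, 256, (8, 8, 3))
            ours = motion_mask(Frame(1, pa), Frame(2, pb), params)
            ref = motion_mask_bruteforce(pa, pb, params.blur_kernel,
                                         params.dilate_kernel,
                                         params.diff_threshold,
                                         params.effective_sigma)
            np.testing.assert_array_equal(ours, ref)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        pa = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        pb = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        counts = [motion_mask(Frame(1, pa), Frame(2, pb),
                              MotionParams(diff_threshold=t)).sum()
                  for t in (5, 20, 60, 120)]
        assert counts == sorted(counts, reverse=True)

    def test_min_area_monotonicity_and_determinism(self):
        rng = np.random.default_rng(4)
        pa = rng.integers(0, 256, (96, 96)).astype(np.uint8)
        pb = pa.copy()
        for _ in range(4):
            r, c = rng.integers(0, 60, 2)
            pb[r:r + 30, c:c + 30] = rng.integers(0, 256)
        ns = []
        for area in (10.0, 100.0, 400.0, 2000.0):
            p = MotionParams(min_contour_area=area)
            regs = detect_motion_regions(Frame(1, pa), Frame(2, pb), p)
            regs2 = detect_motion_regions(Frame(1, pa), Frame(2, pb), p)
            assert [(r.x, r.y, r.w, r.h, r.area) for r in regs] == \
                   [(r.x, r.y, r.w, r.h, r.area) for r in regs2]
            # fixed ordering: by (y, x), then area descending
            keys = [(r.y, r.x, -r.area) for r in regs]
            assert keys == sorted(keys)
            ns.append(len(regs))
        assert ns == sorted(ns, reverse=True)


class TestContours:
    def test_filled_rectangle_polygon_area(self):
        # boundary through pixel centers of a filled w×h block: (w-1)(h-1)
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 3:24] = True  # 10 rows × 21 cols
        contour = simplify_contour(trace_boundary(mask))
        assert polygon_area(contour) == pytest.approx(9 * 20)
        # simplification collapses the rectangle to its 4 corners
        assert len(contour) == 4

    def test_single_pixel_component(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        contour = trace_boundary(mask)
        assert contour.shape == (1, 2)
        assert polygon_area(contour) == 0.0

    def test_area_boundary_exact(self):
        # 334×4 block → polygon area 333×3 = 999 (discarded at 1000);
        # 251×5 block → 250×4 = 1000 (retained).
        m999 = np.zeros((340, 10), dtype=bool)
        m999[3:337, 3:7] = True
        assert find_motion_contours(m999, 1000.0) == []
        m1000 = np.zeros((260, 10), dtype=bool)
        m1000[3:254, 2:7] = True
        (region,) = find_motion_contours(m1000, 1000.0)
        assert region.area == pytest.approx(1000.0)
        assert (region.w, region.h) == (5, 251)

    def test_simplification_preserves_area(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            mask = np.zeros((30, 30), dtype=bool)
            r, c = rng.integers(2, 15, 2)
            hh, ww = rng.integers(3, 12, 2)
            mask[r:r + hh, c:c + ww] = True
            mask[r + hh // 2, c:c + ww + 3] = True  # spur
            raw = trace_boundary(mask)
            assert polygon_area(simplify_contour(raw)) == \
                pytest.approx(polygon_area(raw))


class TestRegionCenter:
    @pytest.mark.parametrize("x,y,w,h,expected", [
        (10, 20, 4, 6, (12.0, 23.0)),
        (0, 0, 1, 1, (0.5, 0.5)),
    ])
    def test_formula(self, x, y, w, h, expected):
        region = MotionRegion(x, y, w, h, np.zeros((1, 2)), 0.0)
        assert region_center(region) == expected

    @given(x=st.integers(0, 500), y=st.integers(0, 500),
           w=st.integers(1, 300), h=st.integers(1, 300))
    def test_real_valued_no_truncation(self, x, y, w, h):
        region = MotionRegion(x, y, w, h, np.zeros((1, 2)), 0.0)
        cx, cy = region_center(region)
        assert cx == x + w / 2 and cy == y + h / 2


def test_scaled_min_area_reference_geometry():
    assert scaled_min_area((1080, 1920)) == pytest.approx(1000.0)
    assert scaled_min_area((240, 320)) == pytest.approx(1000 * 240 * 320 /
                                                        (1080 * 1920))
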