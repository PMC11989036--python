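import math

import numpy as np
import pytest

from iccquant.detect import (ClassicalDetector, Component, DetectorParams,
                             HDAB_BASIS, extract_components, fit_oriented_box,
                             get_detector, register_detector, rgb_from_stains,
                             score_component, separate_stains)
from iccquant.errors import ValidationError
from iccquant.evaluate import match
from iccquant.geometry import obb_iou
from iccquant.imgio import RasterImage
from iccquant.synthdata import SynthSpec, generate_image


class TestSeparateStains:
    def test_white_pixel_has_no_dab(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        st = separate_stains(img)
        assert np.all(st.dab_od < 5e-3)
        assert np.all(st.haematoxylin_od < 5e-3)

    def test_synthesize_then_unmix_roundtrip(self):
        # pure-DAB pixels at known OD must unmix back exactly
        # (unquantized float path: the inverse of the rendering model)
        for d in (0.1, 0.35, 0.8, 1.2):
            dab = np.full((3, 3), d)
            rgb = rgb_from_stains(np.zeros_like(dab), dab, quantize=False)
            st = separate_stains(rgb)
            np.testing.assert_allclose(st.dab_od, d, atol=1e-6)
            np.testing.assert_allclose(st.haematoxylin_od, 0.0, atol=1e-6)

    def test_quantized_roundtrip_close(self):
        # through uint8 quantization the recovery is approximate
        dab = np.full((3, 3), 0.5)
        rgb = rgb_from_stains(np.zeros_like(dab), dab)
        st = separate_stains(rgb)
        np.testing.assert_allclose(st.dab_od, 0.5, atol=0.02)

    def test_haematoxylin_only_pixel_has_no_dab(self):
        h = np.full((2, 2), 0.7)
        rgb = rgb_from_stains(h, np.zeros_like(h), quantize=False)
        st = separate_stains(rgb)
        assert np.all(st.dab_od <= 0.02)
        np.testing.assert_allclose(st.haematoxylin_od, 0.7, atol=1e-6)


def _paint_rotated_rect(shape, cx, cy, w, h, theta, value=1.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    c, s = math.cos(theta), math.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return np.where((np.abs(u) <= w / 2) & (np.abs(v) <= h / 2), value, 0.0)


class TestExtractComponents:
    def test_zero_map(self):
        assert extract_components(np.zeros((50, 50)), DetectorParams()) == []

    def test_single_rotated_blob(self):
        od = _paint_rotated_rect((100, 100), 50, 50, 30, 10, 0.5)
        comps = extract_components(od, DetectorParams())
        assert len(comps) == 1
        assert comps[0].area == pytest.approx(300, rel=0.1)

    def test_bridge_removed_by_opening(self):
        od = np.zeros((60, 120))
        od[20:40, 10:40] = 1.0
        od[20:40, 70:100] = 1.0
        od[29, 40:70] = 1.0  # 1-px bridge
        params = DetectorParams(open_radius_px=2, min_elongation=1.0)
        assert len(extract_components(od, params)) == 2
        # without opening the bridge joins them
        params0 = DetectorParams(open_radius_px=0, min_elongation=1.0)
        assert len(extract_components(od, params0)) == 1

    def test_area_bounds(self):
        od = np.zeros((60, 60))
        od[10:12, 10:12] = 1.0  # 4 px: below min_area
        od[30:50, 10:50] = 1.0  # 800 px
        params = DetectorParams(min_area_px=30, max_area_px=500,
                                open_radius_px=0, min_elongation=1.0)
        assert extract_components(od, params) == []  # 800 > max, 4 < min

    def test_round_blob_rejected_by_elongation(self):
        od = _paint_rotated_rect((60, 60), 30, 30, 12, 12, 0.0)
        params = DetectorParams(open_radius_px=0, min_elongation=1.2)
        assert extract_components(od, params) == []


class TestFitOrientedBox:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 5:25] = True  # 20 wide x 10 tall
        box = fit_oriented_box(mask)
        assert box.w == pytest.approx(20, abs=1)
        assert box.h == pytest.approx(10, abs=1)
        assert abs(box.theta) < math.radians(2)
        assert box.cx == pytest.approx(15, abs=0.5)
        assert box.cy == pytest.approx(15, abs=0.5)

    def test_rotated_rectangle_angle(self):
        theta = math.radians(30)
        od = _paint_rotated_rect((100, 100), 50, 50, 40, 14, theta)
        box = fit_oriented_box(od > 0)
        err = abs(math.remainder(box.theta - theta, math.pi))
        assert err < math.radians(2)
        assert box.w == pytest.approx(40, abs=1.5)
        assert box.h == pytest.approx(14, abs=1.5)

    def test_contains_component_pixels(self, rng):
        # fitted box covers >= 99% of the component's pixels
        for _ in range(20):
            theta = rng.uniform(-math.pi / 2, math.pi / 2)
            w, h = rng.uniform(10, 40), rng.uniform(5, 15)
            od = _paint_rotated_rect((80, 80), 40, 40, w, h, theta)
            coords = np.column_stack(np.nonzero(od))
            box = fit_oriented_box(coords)
            c, s = math.cos(box.theta), math.sin(box.theta)
            dx = coords[:, 1] + 0.5 - box.cx
            dy = coords[:, 0] + 0.5 - box.cy
            u = dx * c + dy * s
            v = -dx * s + dy * c
            inside = (np.abs(u) <= box.w / 2 + 1e-9) & (np.abs(v) <= box.h / 2 + 1e-9)
            assert inside.mean() >= 0.99

    def test_collinear_fallback(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 3:15] = True  # single-row line
        box = fit_oriented_box(mask)
        assert box.w == pytest.approx(12, abs=0.5)
        assert box.h == pytest.approx(1.0, abs=0.5)

    def test_too_small(self):
        with pytest.raises(ValidationError):
            fit_oriented_box(np.array([[1, 1], [2, 2]]))


class TestScoreComponent:
    def test_zero(self):
        dab = np.zeros((10, 10))
        comp = Component(np.array([[1, 1], [1, 2], [2, 1]]))
        assert score_component(comp, dab) == 0.0

    def test_saturates_at_one(self):
        dab = np.full((10, 10), 2.5)
        comp = Component(np.array([[1, 1], [1, 2], [2, 1]]))
        assert score_component(comp, dab) == 1.0

    def test_linear_below_saturation(self):
        dab = np.full((10, 10), 0.4)
        comp = Component(np.array([[1, 1], [1, 2], [2, 1]]))
        assert score_component(comp, dab) == pytest.approx(0.4)


class TestClassicalDetector:
    def test_blank_tile_empty(self):
        tile = RasterImage(np.full((128, 128, 3), 255, dtype=np.uint8))
        assert ClassicalDetector().detect(tile) == []

    def test_contract_on_synthetic_tile(self):
        img, _, _ = generate_image(SynthSpec(seed=5, width=512, height=512,
                                             n_cells=8, n_distractors=10))
        boxes = ClassicalDetector().detect(img)
        for b in boxes:
            assert b.w > 0 and b.h > 0
            assert 0.0 <= b.score <= 1.0
            assert -math.pi / 2 <= b.theta < math.pi / 2

    def test_recovers_ground_truth(self):
        img, gt, _ = generate_image(SynthSpec(seed=0, width=512, height=512,
                                              n_cells=10, n_distractors=15))
        preds = ClassicalDetector().detect(img)
        m = match(preds, gt, 0.5)
        assert int(m.tp_flags.sum()) >= 9

    def test_ignores_haematoxylin_distractors(self):
        img, gt, _ = generate_image(SynthSpec(seed=2, width=512, height=512,
                                              n_cells=0, n_distractors=40))
        assert gt == []
        assert ClassicalDetector().detect(img) == []

    def test_deterministic(self):
        img, _, _ = generate_image(SynthSpec(seed=7, width=256, height=256,
                                             n_cells=3, n_distractors=5))
        a = ClassicalDetector().detect(img)
        b = ClassicalDetector().detect(img)
        assert a == b


class TestRegistry:
    def test_classical_registered(self):
        det = get_detector("classical", params=DetectorParams(dab_od_thresh=0.2))
        assert isinstance(det, ClassicalDetector)
        assert det.params.dab_od_thresh == 0.2

    def test_unknown_name(self):
        with pytest.raises(ValidationError):
            get_detector("neural-net-of-the-future")

    def test_user_registration(self):
        class Null:
            def detect(self, image):
                return []
        register_detector("null", Null)
        assert get_detector("null").detect(None) == []
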