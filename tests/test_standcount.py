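"""Annotation conversion, classical counters, IoU matching, detector harness."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beanpheno.standcount import (AnnotationSet, Box, MockDetector, box_iou,
                                  convert_annotations, count_by_contours,
                                  count_by_watershed, detection_metrics,
                                  match_detections, pseudo_label, read_coco,
                                  rescale_with_boxes, run_detector, write_coco)
from beanpheno.synth import gen_disk_mask


def _via_csv(tmp_path, rows):
    header = ("filename,file_size,file_attributes,region_count,region_id,"
              "region_shape_attributes,region_attributes")
    path = tmp_path / "via.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestConvertAnnotations:
    def test_field_mapping(self, tmp_path):
        row = ('plot1.png,1,"{}",1,0,'
               '"{""name"":""rect"",""x"":10,""y"":20,""width"":30,""height"":40}","{}"')
        sets = convert_annotations(_via_csv(tmp_path, [row]))
        assert len(sets) == 1
        b = sets[0].boxes[0]
        assert (b.x, b.y, b.w, b.h) == (10, 20, 30, 40)
        assert sets[0].plot_id == "plot1"

    def test_empty_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert convert_annotations(path) == []

    def test_grouping_by_image(self, tmp_path):
        rows = [f'p.png,1,"{{}}",3,{i},'
                f'"{{""name"":""rect"",""x"":{10 * i},""y"":0,""width"":5,""height"":5}}","{{}}"'
                for i in range(3)]
        sets = convert_annotations(_via_csv(tmp_path, rows))
        assert len(sets) == 1
        assert len(sets[0].boxes) == 3

    def test_non_rect_region_named_in_error(self, tmp_path):
        row = ('p.png,1,"{}",1,0,'
               '"{""name"":""circle"",""cx"":5,""cy"":5,""r"":2}","{}"')
        with pytest.raises(ValueError, match="row 0"):
            convert_annotations(_via_csv(tmp_path, [row]))


class TestRescaleWithBoxes:
    def test_2x_upscale(self, rng):
        img = rng.integers(0, 255, (50, 100, 3), dtype=np.uint8)
        _, boxes = rescale_with_boxes(img, [Box(10, 20, 30, 20)], target=(200, 100))
        b = boxes[0]
        assert (b.x, b.y, b.w, b.h) == (20, 40, 60, 40)

    def test_identity_target(self, rng):
        img = rng.integers(0, 255, (50, 100, 3), dtype=np.uint8)
        out, boxes = rescale_with_boxes(img, [Box(1, 2, 3, 4)], target=(100, 50))
        assert out.shape == img.shape
        assert (boxes[0].x, boxes[0].y, boxes[0].w, boxes[0].h) == (1, 2, 3, 4)

    def test_non_uniform_scale_per_axis(self, rng):
        img = rng.integers(0, 255, (50, 100, 3), dtype=np.uint8)
        _, boxes = rescale_with_boxes(img, [Box(10, 20, 30, 20)], target=(200, 50))
        b = boxes[0]
        assert (b.x, b.w) == (20, 60)      # width doubled
        assert (b.y, b.h) == (20, 20)      # height untouched
        # box area scales by the product of the axis factors
        assert b.area == pytest.approx(Box(10, 20, 30, 20).area * 2 * 1)

    def test_zero_target_rejected(self, rng):
        with pytest.raises(ValueError):
            rescale_with_boxes(np.zeros((4, 4, 3)), [], target=(0, 10))


class TestClassicalCounters:
    def test_empty_mask_counts_zero(self):
        empty = np.zeros((64, 64), dtype=np.uint8)
        assert count_by_contours(empty).count == 0
        assert count_by_watershed(empty).count == 0

    def test_single_disk(self):
        mask, _ = gen_disk_mask(1, seed=0)
        assert count_by_contours(mask).count == 1
        assert count_by_watershed(mask).count == 1

    def test_three_separated_disks_contours(self):
        mask, _ = gen_disk_mask(3, seed=1)
        result = count_by_contours(mask)
        # connected-component oracle on the generated mask itself
        from skimage.measure import label
        assert label(mask).max() == 3
        assert result.count == 3

    def test_three_disks_watershed_tight_spacing(self):
        mask, _ = gen_disk_mask(3, spacing=100, seed=2)
        assert count_by_watershed(mask).count == 3

    def test_watershed_splits_touching_pair(self):
        # two overlapping disks (radius 30, centers 50 px apart): one merged
        # blob whose two distance-map peaks are >= min_distance 40 apart
        yy, xx = np.mgrid[0:200, 0:200]
        mask = ((((xx - 75) ** 2 + (yy - 100) ** 2) <= 900)
                | (((xx - 125) ** 2 + (yy - 100) ** 2) <= 900)).astype(np.uint8)
        from skimage.measure import label
        assert label(mask).max() == 1          # merged into one blob
        assert count_by_watershed(mask).count == 2

    def test_watershed_exact_on_random_well_separated_disks(self):
        # pairwise center distance > max(2*radius, min_distance) by construction
        for k in (0, 2, 5, 11, 20):
            mask, _ = gen_disk_mask(k, radius=15, spacing=90, seed=100 + k)
            assert count_by_watershed(mask).count == k

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            count_by_watershed(np.full((8, 8), 255, dtype=np.uint8))


class TestBoxIoU:
    @pytest.mark.parametrize("a, b, expected", [
        (Box(0, 0, 10, 10), Box(0, 0, 10, 10), 1.0),
        (Box(0, 0, 10, 10), Box(20, 20, 10, 10), 0.0),
        (Box(0, 0, 10, 10), Box(5, 0, 10, 10), 1 / 3),
    ])
    def test_values(self, a, b, expected):
        assert box_iou(a, b) == pytest.approx(expected)

    def test_symmetric_bounded_and_matches_rasterization(self, rng):
        def raster_iou(a, b):
            w = int(max(a.x + a.w, b.x + b.w)) + 1
            h = int(max(a.y + a.h, b.y + b.h)) + 1
            ga = np.zeros((h, w), bool)
            gb = np.zeros((h, w), bool)
            ga[int(a.y):int(a.y + a.h), int(a.x):int(a.x + a.w)] = True
            gb[int(b.y):int(b.y + b.h), int(b.x):int(b.x + b.w)] = True
            union = (ga | gb).sum()
            return (ga & gb).sum() / union if union else 0.0

        for _ in range(200):
            a = Box(*rng.integers(0, 40, 2), *rng.integers(1, 30, 2))
            b = Box(*rng.integers(0, 40, 2), *rng.integers(1, 30, 2))
            iou = box_iou(a, b)
            assert iou == pytest.approx(box_iou(b, a))
            assert 0 <= iou <= 1
            assert iou == pytest.approx(raster_iou(a, b), abs=1e-12)


class TestMatchDetections:
    def test_perfect_match(self):
        gt = AnnotationSet("p", [Box(0, 0, 10, 10)])
        pred = AnnotationSet("p", [Box(0, 0, 10, 10, score=0.9)])
        m = match_detections(pred, gt)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_two_predictions_one_gt_is_one_to_one(self):
        gt = AnnotationSet("p", [Box(0, 0, 10, 10)])
        pred = AnnotationSet("p", [Box(0, 0, 10, 10, score=0.9),
                                   Box(1, 0, 10, 10, score=0.8)])
        m = match_detections(pred, gt)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_below_threshold_is_fp_and_fn(self):
        gt = AnnotationSet("p", [Box(0, 0, 10, 10)])
        pred = AnnotationSet("p", [Box(6, 0, 10, 10, score=0.9)])  # IoU 4/16 = 0.25
        m = match_detections(pred, gt, iou_threshold=0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_count_conservation_on_random_scenarios(self, rng):
        for _ in range(100):
            n_gt, n_pred = rng.integers(0, 15, 2)
            gt = AnnotationSet("p", [Box(*rng.integers(0, 80, 2), *rng.integers(2, 20, 2))
                                     for _ in range(n_gt)])
            pred = AnnotationSet("p", [Box(*rng.integers(0, 80, 2), *rng.integers(2, 20, 2),
                                           score=float(rng.random()))
                                       for _ in range(n_pred)])
            m = match_detections(pred, gt)
            assert m.tp + m.fn == n_gt
            assert m.tp + m.fp == n_pred

    def test_hungarian_agrees_on_unambiguous_fixture(self):
        gt = AnnotationSet("p", [Box(0, 0, 10, 10), Box(50, 50, 10, 10)])
        pred = AnnotationSet("p", [Box(1, 0, 10, 10, score=0.9),
                                   Box(51, 50, 10, 10, score=0.8)])
        g = match_detections(pred, gt, method="greedy")
        h = match_detections(pred, gt, method="hungarian")
        assert (g.tp, g.fp, g.fn) == (h.tp, h.fp, h.fn) == (2, 0, 0)
        assert g.pairs == h.pairs

    def test_plot_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_detections(AnnotationSet("a", []), AnnotationSet("b", []))


class TestDetectionMetrics:
    def test_count_arithmetic(self):
        d = detection_metrics(tp=3, fp=1, fn=1)
        assert d.precision == pytest.approx(0.75)
        assert d.recall == pytest.approx(0.75)
        assert d.f1 == pytest.approx(0.75)
        assert d.accuracy == pytest.approx(0.6)

    def test_field_rates_worked_example(self):
        # rates in percent: TP 76.1, FP 5.08, FN 18.8
        d = detection_metrics(tp=76.1, fp=5.08, fn=18.8)
        assert d.precision == pytest.approx(0.9374, abs=5e-5)
        assert d.recall == pytest.approx(0.8019, abs=5e-5)
        assert d.accuracy == pytest.approx(0.76, abs=5e-3)

    def test_perfect_detection(self):
        d = detection_metrics(tp=5, fp=0, fn=0)
        assert d.precision == d.recall == d.f1 == d.accuracy == 1.0

    def test_all_zero_counts_are_nan(self):
        d = detection_metrics(tp=0, fp=0, fn=0)
        assert np.isnan(d.precision) and np.isnan(d.recall) and np.isnan(d.f1)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_identities(self, tp, fp, fn):
        d = detection_metrics(tp=tp, fp=fp, fn=fn)
        if np.isfinite(d.f1) and d.precision + d.recall > 0:
            assert d.f1 == pytest.approx(
                2 / (1 / d.precision + 1 / d.recall) if d.precision * d.recall else 0.0)
        if np.isfinite(d.accuracy) and np.isfinite(d.precision) and np.isfinite(d.recall):
            assert d.accuracy <= min(d.precision, d.recall) + 1e-12


class TestDetectorHarness:
    def _layout(self, n=5, pid="p0"):
        return AnnotationSet(pid, [Box(10 + 30 * i, 10, 12, 12) for i in range(n)])

    def test_pseudo_label_score_filter(self):
        class TwoBoxDetector:
            def detect(self, images):
                return [[Box(0, 0, 5, 5, score=0.9), Box(10, 0, 5, 5, score=0.4)]]

        sets = pseudo_label(TwoBoxDetector(), [np.zeros((20, 20, 3))],
                            score_threshold=0.5)
        assert len(sets[0].boxes) == 1
        assert sets[0].provenance == "pseudo"

    def test_pseudo_label_gt_agreement_mode(self):
        class OneGoodOneStray:
            def detect(self, images):
                return [[Box(0, 0, 10, 10, score=0.9), Box(50, 50, 5, 5, score=0.9)]]

        ref = [AnnotationSet("plot_0000", [Box(1, 0, 10, 10)])]
        sets = pseudo_label(OneGoodOneStray(), [np.zeros((80, 80, 3))],
                            plot_ids=["plot_0000"], reference=ref)
        assert len(sets[0].boxes) == 1
        assert sets[0].boxes[0].x == 0

    def test_no_detections_empty_set(self):
        class NullDetector:
            def detect(self, images):
                return [[] for _ in images]

        sets = pseudo_label(NullDetector(), [np.zeros((20, 20, 3))])
        assert sets[0].boxes == []

    def test_run_detector_keeps_low_scores_above_0p1(self):
        class FlatDetector:
            def detect(self, images):
                return [[Box(i, 0, 5, 5, score=0.2) for i in range(0, 400, 5)]]

        sets = run_detector(FlatDetector(), [np.zeros((20, 400, 3))])
        assert len(sets[0].boxes) == 80
        assert sets[0].provenance == "predicted"

    def test_scores_straddling_threshold(self):
        class StraddleDetector:
            def detect(self, images):
                return [[Box(0, 0, 5, 5, score=s)
                         for s in (0.05, 0.1, 0.15, 0.09, 0.5)]]

        sets = run_detector(StraddleDetector(), [np.zeros((20, 20, 3))],
                            detection_threshold=0.1)
        assert len(sets[0].boxes) == 3

    def test_detector_failure_propagated_with_id(self):
        class BrokenDetector:
            def detect(self, images):
                raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="plotX"):
            run_detector(BrokenDetector(), [np.zeros((4, 4, 3))], plot_ids=["plotX"])

    def test_mock_detector_deterministic_and_matchable(self):
        layout = self._layout()
        det = MockDetector([layout], seed=3, jitter_px=1.0)
        img = np.zeros((40, 200, 3), dtype=np.uint8)
        d1 = det.detect([img])
        d2 = det.detect([img])
        assert d1 == d2
        pred = run_detector(det, [img], plot_ids=["p0"])[0]
        m = match_detections(pred, layout, iou_threshold=0.5)
        assert m.tp == len(layout.boxes)


class TestCocoIO:
    def test_roundtrip(self, tmp_path):
        sets = [AnnotationSet("plotA", [Box(1, 2, 3, 4, score=0.7)],
                              image_size=(640, 3872), provenance="predicted")]
        path = tmp_path / "boxes.json"
        write_coco(path, sets)
        loaded = read_coco(path)
        assert loaded[0].plot_id == "plotA"
        b = loaded[0].boxes[0]
        assert (b.x, b.y, b.w, b.h, b.score) == (1, 2, 3, 4, 0.7)
        assert loaded[0].provenance == "predicted"
        coco = json.loads(path.read_text())
        assert coco["categories"][0]["name"] == "bean"
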