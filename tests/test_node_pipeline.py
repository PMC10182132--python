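"""Node detection, cropping, IoU matching, and slide reporting."""

import numpy as np
import pytest

from dtdsmil.errors import DataError, ParseError
from dtdsmil.node_pipeline import (Detection, NodeResult, crop_node,
                                   evaluate_node_stage, export_detections,
                                   import_detections, iou, match_detections,
                                   reference_detect, report_slide)
from dtdsmil.synthdata import SyntheticSlideSpec, gen_slide_raster
from dtdsmil.tiling import SlideRaster


def blob_raster(blobs, shape=(200, 200)):
    """Gray background with saturated red rectangles at given boxes."""
    img = np.full(shape + (3,), 180, dtype=np.uint8)
    for (x0, y0, x1, y1) in blobs:
        img[y0:y1, x0:x1] = (220, 40, 60)
    return SlideRaster(img, 4.0, "5x", "blobs")


class TestReferenceDetect:
    def test_three_disjoint_blobs_found(self):
        dets = reference_detect(blob_raster([(10, 10, 40, 40),
                                             (80, 20, 120, 60),
                                             (30, 120, 90, 170)]),
                                min_area_px=50)
        assert len(dets) == 3
        assert all(d.tissue_class == "lymph_node" and d.confidence == 1.0
                   for d in dets)

    def test_small_blob_dropped_by_min_area(self):
        dets = reference_detect(blob_raster([(10, 10, 40, 40),
                                             (80, 20, 120, 60),
                                             (150, 150, 155, 155)]),
                                min_area_px=100)
        assert len(dets) == 2

    def test_touching_blobs_merge(self):
        dets = reference_detect(blob_raster([(10, 10, 40, 40),
                                             (40, 10, 70, 40)]),
                                min_area_px=50)
        assert len(dets) == 1

    def test_blank_slide_gives_empty_list(self):
        assert reference_detect(blob_raster([])) == []


class TestDetectionIO:
    def test_round_trip_identity(self, tmp_path):
        dets = [Detection((1, 2, 30, 40), "lymph_node", 0.9),
                Detection((50, 60, 70, 80), "other_tissue", 0.5)]
        path = tmp_path / "dets.csv"
        export_detections(dets, path, "s1")
        loaded = import_detections(path)
        assert [d.bbox for d in loaded] == [d.bbox for d in dets]
        assert [d.tissue_class for d in loaded] == ["lymph_node",
                                                    "other_tissue"]
        assert all(d.source == "external" for d in loaded)

    def test_invalid_box_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("slide_id,x_min,y_min,x_max,y_max\ns,5,5,4,9\n")
        with pytest.raises(ParseError, match="row 0"):
            import_detections(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert import_detections(path) == []


class TestCropNode:
    def test_scale_one_is_exact_crop(self, rng):
        pixels = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        raster = SlideRaster(pixels, 2.0, "5x", "s")
        crop = crop_node(raster, Detection((4, 8, 20, 30)), scale_factor=1.0)
        np.testing.assert_array_equal(crop.pixels, pixels[8:30, 4:20])

    def test_scale_four_coordinate_arithmetic(self, rng):
        pixels = rng.integers(0, 256, (80, 80, 3), dtype=np.uint8)
        raster = SlideRaster(pixels, 0.5, "20x", "s")
        crop = crop_node(raster, Detection((0, 0, 10, 10)), scale_factor=4.0)
        assert crop.pixels.shape == (40, 40, 3)

    def test_protruding_box_clipped_with_warning(self, rng):
        pixels = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        raster = SlideRaster(pixels, 1.0, "5x", "s")
        with pytest.warns(UserWarning):
            crop = crop_node(raster, Detection((8, 8, 20, 20)), scale_factor=4.0)
        assert crop.pixels.shape == (8, 8, 3)

    def test_disjoint_box_rejected(self, rng):
        raster = SlideRaster(np.zeros((10, 10, 3), np.uint8), 1.0, "5x")
        with pytest.raises(DataError):
            crop_node(raster, Detection((20, 20, 30, 30)), scale_factor=1.0)


class TestMatching:
    def test_greedy_matches_obvious_assignment(self):
        gt = [(0, 0, 10, 10), (50, 50, 60, 60)]
        det = [(49, 50, 60, 60), (1, 0, 10, 10)]
        assert match_detections(det, gt) == [1, 0]

    def test_low_iou_left_unmatched(self):
        assert match_detections([(0, 0, 10, 10)], [(9, 9, 30, 30)]) == [None]

    def test_agrees_with_exhaustive_assignment_on_small_cases(self, rng):
        from itertools import permutations
        for _ in range(20):
            gt = [(x, y, x + 20, y + 20) for x, y in
                  rng.integers(0, 150, size=(3, 2))]
            det = [(x + int(rng.integers(-3, 4)), y + int(rng.integers(-3, 4)),
                    x + 20 + int(rng.integers(-3, 4)),
                    y + 20 + int(rng.integers(-3, 4)))
                   for (x, y, _, _) in gt]
            greedy = match_detections(det, gt)
            best, best_total = None, -1.0
            for perm in permutations(range(3)):
                total = sum(iou(det[i], gt[perm[i]])
                            for i in range(3)
                            if iou(det[i], gt[perm[i]]) >= 0.5)
                if total > best_total:
                    best_total = total
                    best = [perm[i] if iou(det[i], gt[perm[i]]) >= 0.5
                            else None for i in range(3)]
            assert greedy == best


def fake_result(bbox, c, true_label=None):
    from dtdsmil.dsmil_head import MILOutput
    out = MILOutput(instance_scores=np.array([c]), critical_index=0,
                    attention=np.array([1.0]), f_slide=np.zeros(2),
                    c_max=c, c_slide=c, c=c)
    return NodeResult(detection=Detection(bbox), node_id="n",
                      mil_output=out, predicted_label=int(c > 0.5),
                      true_label=true_label)


class TestEvaluateNodeStage:
    def test_perfect_detector_and_classifier(self):
        gt = [(0, 0, 10, 10), (30, 30, 50, 50)]
        results = [fake_result(gt[0], 0.95), fake_result(gt[1], 0.05)]
        rep = evaluate_node_stage(results, 0.5, gt_boxes=gt, gt_labels=[1, 0])
        assert rep.accuracy == 1.0

    def test_misdetection_predicted_benign_counts_correct(self):
        gt = [(0, 0, 10, 10)]
        results = [fake_result(gt[0], 0.9),
                   fake_result((100, 100, 120, 120), 0.1)]  # background box
        rep = evaluate_node_stage(results, 0.5, gt_boxes=gt, gt_labels=[1])
        assert results[1].true_label == 0  # misdetection labeled benign
        assert rep.accuracy == 1.0

    def test_missing_labels_rejected(self):
        with pytest.raises(DataError):
            evaluate_node_stage([fake_result((0, 0, 5, 5), 0.9)], 0.5)


class TestSlideReport:
    def test_empty(self):
        rep = report_slide("s", [])
        assert rep.n_nodes == 0 and rep.n_positive_nodes == 0

    def test_counts(self):
        results = [fake_result((0, 0, 5, 5), 0.9),
                   fake_result((10, 10, 15, 15), 0.2),
                   fake_result((20, 20, 25, 25), 0.3)]
        rep = report_slide("s", results)
        assert (rep.n_nodes, rep.n_positive_nodes) == (3, 1)
        assert len(rep.node_results) == rep.n_nodes


def test_detected_box_contains_ground_truth_after_upscale():
    from dtdsmil.synthdata import upscale_raster
    spec = SyntheticSlideSpec(n_nodes=2, lesion_class="macro", seed=3)
    raster, boxes, _, masks = gen_slide_raster(spec)
    dets = reference_detect(raster, min_area_px=500)
    assert len(dets) == 2
    hi = upscale_raster(raster, 2)
    for det in dets:
        crop = crop_node(hi, det, scale_factor=2.0)
        assert crop.pixels.size > 0
    # each detection box contains the full node mask footprint
    for (x0, y0, x1, y1) in boxes:
        assert any(d.bbox[0] <= x0 and d.bbox[1] <= y0 and
                   d.bbox[2] >= x1 and d.bbox[3] >= y1 for d in dets)
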