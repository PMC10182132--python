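"""End-to-end synthetic studies.

Two reproducible experiments exercise the full method:

* :func:`bag_benchmark_study` — train DT-DSMIL on the default feature-bag
  benchmark (200 training / 100 held-out bags; see
  :func:`dtdsmil.synthdata.default_benchmark`) and measure held-out bag
  AUROC plus attention-based instance localization (mean per-bag AUROC of
  the attention weights against ground-truth instance labels, over positive
  held-out bags).
* :func:`node_pipeline_study` — render pseudo-slides, detect nodes at low
  magnification, crop each node at 4x scale, train a node-level DT-DSMIL on
  the training slides' node images, classify held-out nodes with a
  validation-derived threshold, and assemble per-slide reports.

The bag generator seed is part of the benchmark definition; the ``seed``
argument controls model initialization and training randomness (and, for
the node study, also the rendered slides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BackboneSpec, FeatureBag, build_backbone
from .model import DTDSMILClassifier, SlideClassifier, default_benchmark_model
from .node_pipeline import (NodeResult, classify_node, crop_node,
                            match_detections, reference_detect, report_slide)
from .synthdata import (SyntheticSlideSpec, default_benchmark,
                        gen_slide_raster, upscale_raster)
from .train_eval import choose_threshold, roc_auc


@dataclass
class BagBenchmarkResult:
    bag_auc: float
    localization_auc: float
    n_test_bags: int
    model: DTDSMILClassifier = field(repr=False, default=None)


def attention_localization_auc(model, bags, bag_labels, instance_labels):
    """Mean per-bag AUROC of attention weights vs. instance labels."""
    per_bag = []
    for bag, il, y in zip(bags, instance_labels, bag_labels):
        if y != 1:
            continue
        out = model.forward_output(bag)
        per_bag.append(roc_auc(out.attention, il))
    return float(np.mean(per_bag))


def bag_benchmark_study(seed: int = 0, mean_shift: float = 2.0,
                        model: DTDSMILClassifier | None = None
                        ) -> BagBenchmarkResult:
    """Train on the default bag benchmark; report held-out metrics."""
    (train_bags, train_labels, _), (test_bags, test_labels, test_inst) = \
        default_benchmark(mean_shift=mean_shift)
    if model is None:
        model = default_benchmark_model(random_state=seed)
    model.fit(train_bags, train_labels)
    scores = model.decision_function(test_bags)
    return BagBenchmarkResult(
        bag_auc=roc_auc(scores, test_labels),
        localization_auc=attention_localization_auc(
            model, test_bags, test_labels, test_inst),
        n_test_bags=len(test_bags),
        model=model)


# -- node pipeline study ---------------------------------------------------

@dataclass
class NodeStudyResult:
    detection_recovery: float     # fraction of planted nodes detected
    n_nodes_true: int
    n_nodes_detected: int
    node_accuracy: float          # per-node label accuracy on held-out slides
    reports_match_ground_truth: bool
    threshold: float
    reports: list = field(repr=False, default_factory=list)


def _slide_nodes(raster, boxes, labels, pipeline: SlideClassifier,
                 scale_factor: float, min_area_px: int,
                 threshold: float | None):
    """Detect, crop at high magnification, and score each node."""
    dets = reference_detect(raster, min_area_px=min_area_px)
    hi = upscale_raster(raster, int(scale_factor))
    match = match_detections([d.bbox for d in dets], boxes)
    results: list[NodeResult] = []
    for k, det in enumerate(dets):
        crop = crop_node(hi, det, scale_factor=scale_factor)
        res = classify_node(crop, pipeline, threshold or 0.5,
                            node_id=f"{raster.slide_id}_n{k}", detection=det)
        res.true_label = int(labels[match[k]]) if match[k] is not None else 0
        results.append(res)
    return dets, results


def node_pipeline_study(seed: int = 0, n_train_slides: int = 10,
                        n_test_slides: int = 6, patch_size: int = 64,
                        scale_factor: float = 4.0, min_area_px: int = 1000,
                        epochs: int = 30) -> NodeStudyResult:
    """Full two-stage study on rendered pseudo-slides.

    Training slides provide labeled node crops for fitting the node-level
    classifier and choosing the decision threshold; held-out slides are
    then processed end to end (detect, crop, classify, report).
    """
    rng_base = (seed * 1000) % (2 ** 31 - 100000)
    backbone = build_backbone(BackboneSpec("tiny_test_cnn", 32, seed=seed))

    def render(n, offset):
        slides = []
        for i in range(n):
            spec = SyntheticSlideSpec(lesion_class="macro",
                                      pos_node_fraction=0.5,
                                      seed=rng_base + offset + i)
            slides.append(gen_slide_raster(spec, f"s{offset + i:03d}"))
        return slides

    train_slides = render(n_train_slides, 0)
    test_slides = render(n_test_slides, 10000)

    # harvest labeled node bags from the training slides
    probe = SlideClassifier(model=None, backbone=backbone,
                            patch_size=patch_size)
    train_bags: list[FeatureBag] = []
    train_labels: list[int] = []
    for raster, boxes, labels, _ in train_slides:
        dets = reference_detect(raster, min_area_px=min_area_px)
        hi = upscale_raster(raster, int(scale_factor))
        match = match_detections([d.bbox for d in dets], boxes)
        for k, det in enumerate(dets):
            crop = crop_node(hi, det, scale_factor=scale_factor)
            train_bags.append(probe.make_bag(crop))
            train_labels.append(int(labels[match[k]])
                                if match[k] is not None else 0)

    clf = DTDSMILClassifier(d_enc=32, n_layers=1, n_heads=4, n_points=4,
                            d_ffn=64, dropout=0.1, epochs=epochs,
                            learning_rate=1e-3, batch_size=4,
                            random_state=seed)
    clf.fit(train_bags, train_labels)
    pipeline = SlideClassifier(clf, backbone, patch_size=patch_size)
    threshold = choose_threshold(clf.decision_function(train_bags),
                                 train_labels)

    # held-out slides end to end
    n_true = n_detected = n_correct = n_nodes = 0
    all_match = True
    reports = []
    for raster, boxes, labels, _ in test_slides:
        dets, results = _slide_nodes(raster, boxes, labels, pipeline,
                                     scale_factor, min_area_px, threshold)
        n_true += len(boxes)
        matched = match_detections([d.bbox for d in dets], boxes)
        n_detected += sum(m is not None for m in matched)
        rep = report_slide(raster.slide_id, results)
        reports.append(rep)
        for r in results:
            n_nodes += 1
            n_correct += int(r.predicted_label == r.true_label)
        if rep.n_nodes != len(boxes) or rep.n_positive_nodes != int(sum(labels)):
            all_match = False
    return NodeStudyResult(
        detection_recovery=n_detected / n_true,
        n_nodes_true=n_true,
        n_nodes_detected=n_detected,
        node_accuracy=n_correct / max(n_nodes, 1),
        reports_match_ground_truth=all_match,
        threshold=float(threshold),
        reports=reports)
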