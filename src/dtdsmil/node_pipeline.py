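"""Two-stage single-lymph-node diagnostic pipeline.

Stage 1 localizes candidate lymph nodes on the low-magnification (5x)
slide.  The trained object detector used clinically is pluggable behind the
:class:`Detection` contract: either the built-in reference detector
(tissue mask -> 8-connected components -> bounding boxes, which does not
discriminate tissue types) or externally computed boxes imported from CSV.
Stage 2 crops each detection from the high-magnification raster (20x, a
factor of 4 from the 5x level) and classifies the single-node image with
the DT-DSMIL model.  For evaluation, detections are matched to ground-truth
boxes greedily by IoU >= 0.5, and tissue misdetected as a lymph node is
assigned a benign true label, mirroring clinical review practice.

Bounding boxes are half-open ``[min, max)`` in pixel coordinates at the 5x
level throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dsmil_head import MILOutput
from .errors import DataError, NoTissueError, ParseError
from .model import SlideClassifier
from .tiling import SlideRaster, compute_tissue_mask
from .train_eval import EvalReport, evaluate_scores

TISSUE_CLASSES = ("lymph_node", "other_tissue")


@dataclass
class Detection:
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), half-open
    tissue_class: str = "lymph_node"
    confidence: float = 1.0
    source: str = "reference_detector"

    def __post_init__(self):
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise DataError(f"degenerate bbox {self.bbox}")
        if self.tissue_class not in TISSUE_CLASSES:
            raise DataError(f"unknown tissue class {self.tissue_class!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise DataError("confidence must lie in [0, 1]")


@dataclass
class NodeResult:
    detection: Detection
    node_id: str
    mil_output: MILOutput | None
    predicted_label: int
    true_label: int | None = None
    no_tissue: bool = False


@dataclass
class SlideReport:
    slide_id: str
    n_nodes: int
    n_positive_nodes: int
    node_results: list[NodeResult] = field(default_factory=list)

    def __post_init__(self):
        if self.n_positive_nodes > self.n_nodes:
            raise DataError("n_positive_nodes cannot exceed n_nodes")


def reference_detect(raster_5x: SlideRaster, min_area_px: int = 64
                     ) -> list[Detection]:
    """Connected-component node proposals on the low-magnification raster.

    Components of the tissue mask (8-connected) with at least
    ``min_area_px`` pixels become detections.  All boxes are labeled
    ``lymph_node`` with confidence 1.0 — this reference detector does not
    discriminate tissue types, and touching structures merge into one box.
    """
    mask = compute_tissue_mask(raster_5x).mask
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    detections = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:
            continue
        region = labeled[sl] > 0
        if region.sum() < min_area_px:
            continue
        y, x = sl
        detections.append(Detection(
            bbox=(x.start, y.start, x.stop, y.stop),
            tissue_class="lymph_node", confidence=1.0,
            source="reference_detector"))
    return detections


def export_detections(detections: list[Detection], path: str | Path,
                      slide_id: str = "slide") -> None:
    rows = [{"slide_id": slide_id, "x_min": d.bbox[0], "y_min": d.bbox[1],
             "x_max": d.bbox[2], "y_max": d.bbox[3],
             "tissue_class": d.tissue_class, "confidence": d.confidence}
            for d in detections]
    pd.DataFrame(rows, columns=["slide_id", "x_min", "y_min", "x_max", "y_max",
                                "tissue_class", "confidence"]).to_csv(
        path, index=False)


def import_detections(path: str | Path) -> list[Detection]:
    """Read externally produced detections; coordinates are validated."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if len(table) == 0:
        return []
    required = {"x_min", "y_min", "x_max", "y_max"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"detections file missing columns {sorted(missing)}")
    detections = []
    for i, row in table.iterrows():
        try:
            detections.append(Detection(
                bbox=(int(row.x_min), int(row.y_min),
                      int(row.x_max), int(row.y_max)),
                tissue_class=row.get("tissue_class", "lymph_node"),
                confidence=float(row.get("confidence", 1.0)),
                source="external"))
        except (DataError, ValueError) as exc:
            raise ParseError(f"invalid detection at row {i}: {exc}") from exc
    return detections


def crop_node(raster_hi: SlideRaster, det: Detection,
              scale_factor: float = 4.0) -> SlideRaster:
    """Crop a detection from the high-magnification raster.

    The 5x-level bbox is scaled by ``scale_factor`` (4 maps 5x to 20x) and
    clipped to the raster bounds with a warning if it protrudes.
    """
    x0, y0, x1, y1 = (int(round(v * scale_factor)) for v in det.bbox)
    H, W = raster_hi.shape
    cx0, cy0 = max(x0, 0), max(y0, 0)
    cx1, cy1 = min(x1, W), min(y1, H)
    if cx1 <= cx0 or cy1 <= cy0:
        raise DataError(f"scaled bbox {(x0, y0, x1, y1)} misses the raster")
    if (cx0, cy0, cx1, cy1) != (x0, y0, x1, y1):
        warnings.warn("scaled bbox clipped to raster bounds", stacklevel=2)
    return SlideRaster(raster_hi.pixels[cy0:cy1, cx0:cx1],
                       raster_hi.microns_per_pixel,
                       raster_hi.magnification_label,
                       f"{raster_hi.slide_id}_node_{cx0}_{cy0}")


def classify_node(node_raster: SlideRaster, model: SlideClassifier,
                  threshold: float, node_id: str = "node",
                  detection: Detection | None = None) -> NodeResult:
    """Score one cropped node image; no-tissue crops are benign by flag."""
    if detection is None:
        H, W = node_raster.shape
        detection = Detection(bbox=(0, 0, W, H))
    try:
        out = model.score(node_raster)
    except NoTissueError:
        return NodeResult(detection=detection, node_id=node_id,
                          mil_output=None, predicted_label=0, no_tissue=True)
    return NodeResult(detection=detection, node_id=node_id, mil_output=out,
                      predicted_label=int(out.c > threshold))


# -- evaluation -----------------------------------------------------------

def iou(box_a, box_b) -> float:
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    ix = max(0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def match_detections(det_boxes, gt_boxes, iou_threshold: float = 0.5
                     ) -> list[int | None]:
    """Greedy highest-IoU-first matching; returns a gt index per detection."""
    pairs = sorted(
        ((iou(d, g), di, gi) for di, d in enumerate(det_boxes)
         for gi, g in enumerate(gt_boxes)),
        key=lambda t: -t[0])
    match: list[int | None] = [None] * len(det_boxes)
    used_gt: set[int] = set()
    for score, di, gi in pairs:
        if score < iou_threshold:
            break
        if match[di] is None and gi not in used_gt:
            match[di] = gi
            used_gt.add(gi)
    return match


def assign_true_labels(results: list[NodeResult], gt_boxes, gt_labels,
                       iou_threshold: float = 0.5) -> list[NodeResult]:
    """Attach true labels by IoU matching; misdetections become benign."""
    match = match_detections([r.detection.bbox for r in results], gt_boxes,
                             iou_threshold)
    for r, gi in zip(results, match):
        r.true_label = int(gt_labels[gi]) if gi is not None else 0
    return results


def evaluate_node_stage(results: list[NodeResult], threshold: float,
                        gt_boxes=None, gt_labels=None,
                        iou_threshold: float = 0.5) -> EvalReport:
    """Node-level evaluation report under the misdetection-is-benign rule.

    If ``gt_boxes``/``gt_labels`` are given, true labels are (re)assigned
    by IoU matching first; otherwise ``results`` must already carry them.
    """
    if gt_boxes is not None:
        if gt_labels is None:
            raise DataError("gt_boxes given without gt_labels")
        results = assign_true_labels(results, gt_boxes, gt_labels,
                                     iou_threshold)
    if any(r.true_label is None for r in results):
        raise DataError("results lack ground-truth labels")
    scores = np.array([r.mil_output.c if r.mil_output is not None else 0.0
                       for r in results])
    labels = np.array([r.true_label for r in results])
    return evaluate_scores(scores, labels, threshold)


def report_slide(slide_id: str, node_results: list[NodeResult]) -> SlideReport:
    """Per-slide summary: how many nodes, and how many called positive."""
    return SlideReport(
        slide_id=slide_id,
        n_nodes=len(node_results),
        n_positive_nodes=int(sum(r.predicted_label for r in node_results)),
        node_results=node_results)


def save_slide_report(report: SlideReport, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{report.slide_id}.report.json"
    path.write_text(json.dumps({
        "slide_id": report.slide_id,
        "n_nodes": report.n_nodes,
        "n_positive_nodes": report.n_positive_nodes,
        "nodes": [{
            "node_id": r.node_id,
            "bbox": list(r.detection.bbox),
            "predicted_label": r.predicted_label,
            "true_label": r.true_label,
            "c": None if r.mil_output is None else r.mil_output.c,
            "no_tissue": r.no_tissue,
        } for r in report.node_results],
    }, indent=2))
    return path
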