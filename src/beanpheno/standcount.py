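"""Early-season stand counting and detection evaluation.

Two classical counters operate on a binary vegetation mask (from ExG - ExR
binarization or any pluggable segmenter):

* contour chain: grayscale -> 5x5 Gaussian blur -> Canny edges (L2 gradient)
  -> dilation with a 5x5 kernel for 100 iterations -> 3x3 morphological
  closing -> external contour count;
* watershed chain: grayscale -> 5x5 Gaussian blur -> Euclidean distance
  transform -> local maxima separated by >= 40 px as markers -> 3x3-connected
  marker labeling -> watershed segmentation; the segment count is the stand
  count.

Around them sit the annotation plumbing (VIA CSV -> COCO-style boxes,
rescaling with boxes), one-to-one IoU matching of predictions against ground
truth, the precision/recall/F1/accuracy metrics, and a pluggable detector
interface with pseudo-labeling (confident predictions on unlabeled plots
recycled as training annotations) and inference at a 0.1 score threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import canny, peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed
from skimage.transform import resize


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, top-left (x, y), half-open extent [x, x+w) x [y, y+h)."""

    x: float
    y: float
    w: float
    h: float
    score: float | None = None
    label: str = "bean"

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box width/height must be > 0, got {self.w}x{self.h}")
        if self.score is not None and not 0 <= self.score <= 1:
            raise ValueError("score must be in [0, 1]")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass
class AnnotationSet:
    plot_id: str
    boxes: list[Box]
    image_size: tuple[int, int] | None = None      # (height, width)
    provenance: str = "manual"                      # manual | pseudo | predicted

    def __post_init__(self) -> None:
        if self.provenance not in ("manual", "pseudo", "predicted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class MatchResult:
    tp: float
    fp: float
    fn: float
    pairs: list[tuple[int, int]] = field(default_factory=list)
    iou_threshold: float = 0.5


@dataclass
class StandCountResult:
    plot_id: str
    method: str
    count: int
    labels: np.ndarray | None = None


# -- annotation formats ---------------------------------------------------

def convert_annotations(via_csv) -> list[AnnotationSet]:
    """Convert a VIA (VGG Image Annotator) CSV export to per-plot box sets.

    Only rectangle regions are accepted; each distinct filename becomes one
    AnnotationSet keyed by the filename stem.
    """
    try:
        df = pd.read_csv(via_csv)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if "filename" not in df.columns or "region_shape_attributes" not in df.columns:
        raise ValueError("not a VIA CSV export: missing filename/region_shape_attributes")
    sets: dict[str, list[Box]] = {}
    for i, row in df.iterrows():
        raw = row["region_shape_attributes"]
        if pd.isna(raw) or raw in ("{}", ""):
            sets.setdefault(Path(str(row["filename"])).stem, [])
            continue
        try:
            shape = json.loads(raw)
        except json.JSONDecodeError as err:
            raise ValueError(f"row {i}: malformed region JSON: {err}") from err
        name = shape.get("name", "rect")
        if name != "rect":
            raise ValueError(f"row {i}: unsupported region shape {name!r} (only rect)")
        box = Box(x=float(shape["x"]), y=float(shape["y"]),
                  w=float(shape["width"]), h=float(shape["height"]))
        sets.setdefault(Path(str(row["filename"])).stem, []).append(box)
    return [AnnotationSet(plot_id=pid, boxes=boxes, provenance="manual")
            for pid, boxes in sets.items()]


def rescale_with_boxes(image: np.ndarray, boxes: Sequence[Box],
                       target: tuple[int, int] = (3872, 640)
                       ) -> tuple[np.ndarray, list[Box]]:
    """Rescale an image to ``target`` (width, height) and its boxes with it."""
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError("target size must be positive")
    if image.size == 0:
        raise ValueError("empty image")
    ih, iw = image.shape[:2]
    sx, sy = tw / iw, th / ih
    out = resize(image.astype(float), (th, tw) + image.shape[2:],
                 order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(image.dtype).min,
                      np.iinfo(image.dtype).max).astype(image.dtype)
    scaled = [replace(b, x=b.x * sx, y=b.y * sy, w=b.w * sx, h=b.h * sy) for b in boxes]
    return out, scaled


def read_coco(path) -> list[AnnotationSet]:
    with open(path) as fh:
        coco = json.load(fh)
    images = {img["id"]: img for img in coco.get("images", [])}
    sets: dict[int, list[Box]] = {img_id: [] for img_id in images}
    for ann in coco.get("annotations", []):
        x, y, w, h = ann["bbox"]
        sets[ann["image_id"]].append(Box(x=x, y=y, w=w, h=h, score=ann.get("score")))
    prov = coco.get("info", {}).get("provenance", "manual")
    return [AnnotationSet(plot_id=str(images[i].get("file_name", i)),
                          boxes=b,
                          image_size=(images[i].get("height"), images[i].get("width")),
                          provenance=prov)
            for i, b in sets.items()]


def write_coco(path, sets: Sequence[AnnotationSet], category: str = "bean") -> None:
    images, annotations = [], []
    ann_id = 1
    provenance = sets[0].provenance if sets else "manual"
    for img_id, s in enumerate(sets, start=1):
        h, w = s.image_size if s.image_size else (None, None)
        images.append({"id": img_id, "file_name": s.plot_id, "height": h, "width": w})
        for b in s.boxes:
            record = {"id": ann_id, "image_id": img_id, "category_id": 1,
                      "bbox": [b.x, b.y, b.w, b.h], "area": b.area, "iscrowd": 0}
            if b.score is not None:
                record["score"] = b.score
            annotations.append(record)
            ann_id += 1
    coco = {"info": {"provenance": provenance},
            "images": images,
            "annotations": annotations,
            "categories": [{"id": 1, "name": category}]}
    with open(path, "w") as fh:
        json.dump(coco, fh)


# -- classical counters ---------------------------------------------------

_BLUR_SIGMA = 1.1  # Gaussian sigma matching a 5x5 kernel


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D binary image")
    if mask.size and mask.max() > 1:
        raise ValueError("mask must contain only {0, 1}")
    return mask.astype(np.uint8)


def count_by_contours(mask: np.ndarray, plot_id: str = "",
                      dilation_iterations: int = 100) -> StandCountResult:
    """Contour-based counter on a binary mask rendered as 0/255 grayscale.

    The 100-fold 5x5 dilation is realized exactly as a single Chebyshev
    dilation of radius 2 x iterations (a square structuring element composes
    to a larger square), and the external-contour count equals the number of
    8-connected components of the closed edge image.
    """
    mask = _check_binary(mask)
    if mask.sum() == 0:
        return StandCountResult(plot_id, "contours", 0)
    gray = ndi.gaussian_filter(mask.astype(float) * 255.0, sigma=_BLUR_SIGMA)
    edges = canny(gray / 255.0, sigma=0)
    if not edges.any():
        return StandCountResult(plot_id, "contours", 0)
    radius = 2 * dilation_iterations
    dist = ndi.distance_transform_cdt(~edges, metric="chessboard")
    dilated = dist <= radius
    closed = ndi.binary_closing(dilated, structure=np.ones((3, 3)))
    labels, n = cc_label(closed, connectivity=2, return_num=True)
    return StandCountResult(plot_id, "contours", int(n), labels)


def count_by_watershed(mask: np.ndarray, min_distance: int = 40,
                       plot_id: str = "") -> StandCountResult:
    """Watershed counter: distance-map peaks seed one segment per plant."""
    mask = _check_binary(mask)
    if mask.sum() == 0:
        return StandCountResult(plot_id, "watershed", 0)
    gray = ndi.gaussian_filter(mask.astype(float) * 255.0, sigma=_BLUR_SIGMA)
    binary = gray > 127.5
    if not binary.any():
        return StandCountResult(plot_id, "watershed", 0)
    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=binary,
                           exclude_border=False)
    if peaks.size == 0:
        return StandCountResult(plot_id, "watershed", 0)
    seed_img = np.zeros_like(dist, dtype=bool)
    seed_img[tuple(peaks.T)] = True
    markers, _ = ndi.label(seed_img, structure=np.ones((3, 3)))
    labels = watershed(-dist, markers, mask=binary)
    return StandCountResult(plot_id, "watershed", int(labels.max()), labels)


# -- IoU matching and metrics ---------------------------------------------

def box_iou(a: Box, b: Box) -> float:
    """Intersection over union on half-open pixel extents; in [0, 1]."""
    ix = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(predictions: AnnotationSet, gt: AnnotationSet,
                     iou_threshold: float = 0.5,
                     method: str = "greedy") -> MatchResult:
    """One-to-one matching of predicted boxes against ground truth.

    Greedy (default): predictions in descending score order each claim the
    unmatched GT box of highest IoU >= threshold.  ``method="hungarian"``
    instead maximizes total IoU with :func:`scipy.optimize.linear_sum_assignment`
    before applying the threshold.
    """
    if predictions.plot_id != gt.plot_id:
        raise ValueError(
            f"plot mismatch: {predictions.plot_id!r} vs {gt.plot_id!r}")
    preds, gts = predictions.boxes, gt.boxes
    if not preds or not gts:
        return MatchResult(tp=0, fp=len(preds), fn=len(gts),
                           iou_threshold=iou_threshold)
    iou = np.array([[box_iou(p, g) for g in gts] for p in preds])
    pairs: list[tuple[int, int]] = []
    if method == "greedy":
        order = sorted(range(len(preds)),
                       key=lambda i: -(preds[i].score if preds[i].score is not None else 1.0))
        taken = np.zeros(len(gts), dtype=bool)
        for i in order:
            row = np.where(taken, -1.0, iou[i])
            j = int(np.argmax(row))
            if row[j] >= iou_threshold:
                taken[j] = True
                pairs.append((i, j))
    elif method == "hungarian":
        from scipy.optimize import linear_sum_assignment
        ri, cj = linear_sum_assignment(-iou)
        pairs = [(int(i), int(j)) for i, j in zip(ri, cj) if iou[i, j] >= iou_threshold]
    else:
        raise ValueError(f"unknown matching method {method!r}")
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp,
                       pairs=sorted(pairs), iou_threshold=iou_threshold)


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    accuracy: float


def detection_metrics(m: MatchResult | None = None, tp: float | None = None,
                      fp: float | None = None, fn: float | None = None) -> DetectionMetrics:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), Ac = TP/(TP+FP+FN).

    Accepts a :class:`MatchResult` or raw counts/rates.  Undefined ratios
    (zero denominators) come back as NaN, never 0.
    """
    if m is not None:
        tp, fp, fn = m.tp, m.fp, m.fn
    if tp is None or fp is None or fn is None:
        raise ValueError("provide a MatchResult or tp, fp, fn")
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else float("nan")
    r = tp / (tp + fn) if tp + fn > 0 else float("nan")
    f1 = 2 * p * r / (p + r) if np.isfinite(p) and np.isfinite(r) and p + r > 0 else float("nan")
    ac = tp / (tp + fp + fn) if tp + fp + fn > 0 else float("nan")
    return DetectionMetrics(precision=p, recall=r, f1=f1, accuracy=ac)


# -- pluggable detector ----------------------------------------------------

class Detector(Protocol):
    """Interface for detection backends (a trained CNN, a mock, ...)."""

    def detect(self, images: Sequence[np.ndarray]) -> list[list[Box]]:
        """Scored boxes per image."""
        ...


class MockDetector:
    """Deterministic detector for harness tests: jitters known layouts.

    Configured with per-plot ground-truth boxes; ``detect`` returns each box
    perturbed by a seeded offset with a seeded score, plus optional spurious
    boxes - enough structure to exercise matching, pseudo-labeling, and
    thresholding without a trained network.
    """

    def __init__(self, layouts: Sequence[AnnotationSet], seed: int = 0,
                 jitter_px: float = 2.0, score_range: tuple[float, float] = (0.3, 1.0),
                 spurious_per_image: int = 0):
        self.layouts = list(layouts)
        self.seed = seed
        self.jitter_px = jitter_px
        self.score_range = score_range
        self.spurious_per_image = spurious_per_image

    def detect(self, images: Sequence[np.ndarray]) -> list[list[Box]]:
        if len(images) != len(self.layouts):
            raise ValueError(
                f"detector configured for {len(self.layouts)} plots, got {len(images)}")
        rng = np.random.default_rng(self.seed)
        lo, hi = self.score_range
        out: list[list[Box]] = []
        for img, layout in zip(images, self.layouts):
            h, w = img.shape[:2]
            boxes = []
            for b in layout.boxes:
                dx, dy = rng.uniform(-self.jitter_px, self.jitter_px, size=2)
                boxes.append(Box(x=min(max(b.x + dx, 0.0), w - b.w),
                                 y=min(max(b.y + dy, 0.0), h - b.h),
                                 w=b.w, h=b.h,
                                 score=float(rng.uniform(lo, hi))))
            for _ in range(self.spurious_per_image):
                bw, bh = rng.uniform(5, 20, size=2)
                boxes.append(Box(x=float(rng.uniform(0, w - bw)),
                                 y=float(rng.uniform(0, h - bh)),
                                 w=float(bw), h=float(bh),
                                 score=float(rng.uniform(0.0, 0.4))))
            out.append(boxes)
        return out


def pseudo_label(detector: Detector, images: Sequence[np.ndarray],
                 plot_ids: Sequence[str] | None = None,
                 score_threshold: float = 0.5,
                 reference: Sequence[AnnotationSet] | None = None,
                 reference_iou: float = 0.5) -> list[AnnotationSet]:
    """Confident detections on unlabeled plots, emitted as training boxes.

    By default boxes are kept by confidence score.  When ``reference`` box
    sets are supplied, a GT-agreement mode applies instead: a detection
    survives only if it overlaps some reference box at IoU >= reference_iou.
    """
    sets = _run(detector, images, plot_ids, score_threshold, provenance="pseudo")
    if reference is not None:
        refs = {r.plot_id: r.boxes for r in reference}
        for s in sets:
            ref_boxes = refs.get(s.plot_id, [])
            s.boxes = [b for b in s.boxes
                       if any(box_iou(b, r) >= reference_iou for r in ref_boxes)]
    return sets


def run_detector(detector: Detector, images: Sequence[np.ndarray],
                 plot_ids: Sequence[str] | None = None,
                 detection_threshold: float = 0.1) -> list[AnnotationSet]:
    """Inference pass; boxes kept at the 0.1 detection threshold."""
    return _run(detector, images, plot_ids, detection_threshold, provenance="predicted")


def _run(detector, images, plot_ids, threshold, provenance):
    if plot_ids is None:
        plot_ids = [f"plot_{i:04d}" for i in range(len(images))]
    if len(plot_ids) != len(images):
        raise ValueError("plot_ids must align with images")
    try:
        detections = detector.detect(images)
    except Exception as err:
        raise RuntimeError(f"detector failed on batch starting at "
                           f"{plot_ids[0] if plot_ids else '?'}: {err}") from err
    out = []
    for pid, img, boxes in zip(plot_ids, images, detections):
        kept = [b for b in boxes if (b.score if b.score is not None else 1.0) >= threshold]
        out.append(AnnotationSet(plot_id=pid, boxes=kept,
                                 image_size=img.shape[:2], provenance=provenance))
    return out
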