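"""Detector scoring: IoU, greedy matching, precision-recall, and
PASCAL-VOC average precision with confidence-threshold sweeps.

The protocol follows the VOC benchmark.  Per class, detections are ranked
by descending confidence and each is greedily matched to the not-yet-
matched ground-truth box of highest IoU *on its own image*; a detection is
a true positive iff that IoU reaches the threshold (default 0.5), else a
false positive.  Every detection on a negative image (one with no
ground-truth objects) is therefore a false positive regardless of score —
this is why evaluation sets are supplemented with explicit negatives.

AP is the area under the monotone precision envelope of the ranked
precision-recall curve.  Two envelope summaries are offered:

* ``all_points`` (default): integrate the envelope over every recall
  change point, as modern VOC-style evaluators do;
* ``eleven_point``: average the envelope at recalls 0.0, 0.1, ..., 1.0
  (the original VOC2007 flavor).

mAP is the unweighted mean of per-class APs; for a single class it equals
the AP.  Sweeping a rising confidence threshold discards low-scoring
detections before matching, which can only lower the envelope integral —
the mAP-versus-threshold curve is non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, BoundingBox

log = logging.getLogger(__name__)

DEFAULT_IOU_THRESHOLD = 0.5
DEFAULT_CONFIDENCE_THRESHOLDS = (0.05, 0.30, 0.50)


class EvaluationError(ValueError):
    """Raised for inconsistent detection/ground-truth inputs."""


@dataclass(frozen=True)
class Detection:
    """One scored predicted box."""

    image_id: str
    class_label: str
    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise EvaluationError(
                f"{self.image_id}: score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class ClassMatch:
    """Ranked match outcome for one class.

    ``detections`` are in evaluation rank order (descending score, ties by
    image_id then box coordinates, a total order independent of input row
    order); ``is_tp[i]`` flags the i-th, and
    ``matched_gt[i]`` names its ground-truth box as (image_id, index) or
    None for a false positive.
    """

    class_label: str
    detections: tuple[Detection, ...]
    is_tp: tuple[bool, ...]
    matched_gt: tuple[tuple[str, int] | None, ...]
    n_gt: int

    @property
    def n_tp(self) -> int:
        return sum(self.is_tp)

    @property
    def n_fp(self) -> int:
        return len(self.is_tp) - self.n_tp

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


@dataclass(frozen=True)
class MatchResult:
    """Per-class match outcomes for one detection set."""

    per_class: Mapping[str, ClassMatch]

    def __getitem__(self, class_label: str) -> ClassMatch:
        return self.per_class[class_label]

    def classes(self) -> list[str]:
        return sorted(self.per_class)


@dataclass(frozen=True)
class EvalReport:
    """AP/mAP summary at one confidence threshold."""

    confidence_threshold: float
    per_class_ap: Mapping[str, float]
    pr_curves: Mapping[str, tuple[tuple[float, float], ...]]  # (recall, precision)
    counts: Mapping[str, tuple[int, int, int]]  # class -> (TP, FP, FN)

    @property
    def map(self) -> float:
        aps = list(self.per_class_ap.values())
        return float(np.mean(aps)) if aps else 0.0

    def to_dict(self) -> dict:
        return {
            "confidence_threshold": self.confidence_threshold,
            "mAP": self.map,
            "per_class_ap": dict(self.per_class_ap),
            "counts": {c: {"tp": t, "fp": f, "fn": n}
                       for c, (t, f, n) in self.counts.items()},
        }


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes (half-open convention).

    Edge-adjacent boxes share no pixels and score 0.
    """
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _ranked(dets: Sequence[Detection]) -> list[Detection]:
    # total order independent of input row order: descending score, then
    # image_id, then box coordinates (exact duplicates are interchangeable)
    return sorted(dets, key=lambda d: (-d.score, d.image_id, d.box.xmin,
                                       d.box.ymin, d.box.xmax, d.box.ymax))


def match_detections(dets: Sequence[Detection],
                     gts: Mapping[str, AnnotationSet],
                     iou_threshold: float = DEFAULT_IOU_THRESHOLD,
                     ) -> MatchResult:
    """Greedily match detections to ground truth, VOC style.

    ``gts`` maps image_id to its annotation set and defines the image
    universe: a detection naming an unknown image is an error, because it
    usually means evaluation is running against the wrong split.  Each
    ground-truth box can absorb at most one detection.
    """
    unknown = sorted({d.image_id for d in dets} - set(gts))
    if unknown:
        raise EvaluationError(
            f"detections reference unknown image_ids: {unknown[:5]}")

    classes = sorted({o.class_label for a in gts.values() for o in a.objects}
                     | {d.class_label for d in dets})
    per_class: dict[str, ClassMatch] = {}
    for cls in classes:
        gt_boxes = {
            img: [o.box for o in ann.objects if o.class_label == cls]
            for img, ann in gts.items()
        }
        n_gt = sum(len(v) for v in gt_boxes.values())
        taken: dict[str, set[int]] = {img: set() for img in gt_boxes}

        ranked = _ranked([d for d in dets if d.class_label == cls])
        flags: list[bool] = []
        matched: list[tuple[str, int] | None] = []
        for d in ranked:
            candidates = gt_boxes.get(d.image_id, [])
            best_iou, best_j = 0.0, -1
            for j, g in enumerate(candidates):
                if j in taken[d.image_id]:
                    continue
                v = iou(d.box, g)
                if v > best_iou:
                    best_iou, best_j = v, j
            if best_j >= 0 and best_iou >= iou_threshold:
                taken[d.image_id].add(best_j)
                flags.append(True)
                matched.append((d.image_id, best_j))
            else:
                flags.append(False)
                matched.append(None)
        per_class[cls] = ClassMatch(cls, tuple(ranked), tuple(flags),
                                    tuple(matched), n_gt)
    return MatchResult(per_class=per_class)


def precision_recall(tp_flags: Sequence[bool],
                     n_gt: int) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative precision and recall over the ranked detections."""
    flags = np.asarray(tp_flags, dtype=bool)
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt if n_gt > 0 else np.zeros(len(flags))
    precision = tp / np.maximum(tp + fp, 1)
    return recall, precision


def average_precision(match: Sequence[bool] | ClassMatch, n_gt: int | None = None,
                      mode: str = "all_points") -> float:
    """VOC average precision from a ranked TP/FP outcome sequence.

    The precision curve is first replaced by its monotone non-increasing
    envelope (each point takes the best precision achieved at that recall
    or beyond).  ``all_points`` integrates the envelope over recall;
    ``eleven_point`` averages it at recalls 0.0, 0.1, ..., 1.0.  With no
    ground truth and no detections the AP is defined as 0 with a warning.
    """
    if isinstance(match, ClassMatch):
        flags: Sequence[bool] = match.is_tp
        n_gt = match.n_gt if n_gt is None else n_gt
    else:
        flags = match
        if n_gt is None:
            raise EvaluationError("n_gt is required with a raw flag sequence")
    if n_gt < 0:
        raise EvaluationError("n_gt must be non-negative")
    if mode not in ("all_points", "eleven_point"):
        raise EvaluationError(f"unknown AP mode {mode!r}")
    if n_gt == 0:
        if len(flags) == 0:
            log.warning("AP undefined with no ground truth and no "
                        "detections; reporting 0")
        return 0.0
    if len(flags) == 0:
        return 0.0

    recall, precision = precision_recall(flags, n_gt)
    # monotone envelope, right to left
    env = np.maximum.accumulate(precision[::-1])[::-1]

    if mode == "eleven_point":
        pts = []
        for r in np.linspace(0.0, 1.0, 11):
            above = env[recall >= r - 1e-12]
            pts.append(float(above.max()) if above.size else 0.0)
        return float(np.mean(pts))

    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def evaluate_at_thresholds(dets: Sequence[Detection],
                           gts: Mapping[str, AnnotationSet],
                           thresholds: Sequence[float] = DEFAULT_CONFIDENCE_THRESHOLDS,
                           iou_threshold: float = DEFAULT_IOU_THRESHOLD,
                           mode: str = "all_points") -> list[EvalReport]:
    """Match and score the detection set at each confidence threshold.

    Detections scoring below a threshold are discarded before matching;
    the surviving set is matched and AP computed per class, and mAP is the
    unweighted class mean.
    """
    if list(thresholds) != sorted(thresholds):
        raise EvaluationError("thresholds must be ascending")
    reports = []
    for t in thresholds:
        kept = [d for d in dets if d.score >= t]
        result = match_detections(kept, gts, iou_threshold)
        aps, curves, counts = {}, {}, {}
        for cls, cm in result.per_class.items():
            aps[cls] = average_precision(cm, mode=mode)
            recall, precision = precision_recall(cm.is_tp, cm.n_gt)
            curves[cls] = tuple(zip(recall.tolist(), precision.tolist()))
            counts[cls] = (cm.n_tp, cm.n_fp, cm.n_fn)
        reports.append(EvalReport(confidence_threshold=float(t),
                                  per_class_ap=aps, pr_curves=curves,
                                  counts=counts))
    return reports


def read_detections_csv(path: str | Path,
                        voc_coords: bool = False) -> list[Detection]:
    """Load detections from CSV: image_id,class_label,score,xmin,ymin,xmax,ymax.

    Coordinates are internal 0-based half-open unless ``voc_coords`` is
    set, in which case 1-based inclusive values are converted on read.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "class_label": str})
    required = ["image_id", "class_label", "score",
                "xmin", "ymin", "xmax", "ymax"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EvaluationError(f"{path}: detections CSV missing {missing}")
    off = 1 if voc_coords else 0
    dets = []
    for row in df.itertuples(index=False):
        box = BoundingBox(int(row.xmin) - off, int(row.ymin) - off,
                          int(row.xmax), int(row.ymax))
        dets.append(Detection(row.image_id, row.class_label, box,
                              float(row.score)))
    return dets


def write_detections_csv(dets: Sequence[Detection], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(d.image_id, d.class_label, d.score, d.box.xmin, d.box.ymin,
          d.box.xmax, d.box.ymax) for d in dets],
        columns=["image_id", "class_label", "score",
                 "xmin", "ymin", "xmax", "ymax"],
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_pr_curves(report: EvalReport, out_dir: str | Path) -> list[Path]:
    """One recall,precision CSV per class for a report's threshold."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tag = f"{int(round(report.confidence_threshold * 100)):03d}"
    for cls, pts in report.pr_curves.items():
        p = out_dir / f"pr_{cls}_t{tag}.csv"
        pd.DataFrame(pts, columns=["recall", "precision"]).to_csv(p, index=False)
        written.append(p)
    return written
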