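"""Evaluation metrics for tooth instance segmentation and labeling.

Detection is scored by matching predicted to annotated teeth with a
point-wise IoU of at least 0.5 (optimal one-to-one assignment), then
F1 = 2TP / (2TP + FP + FN).  Segmentation quality is the mean
point-wise Dice over matched pairs; labeling is macro-F1 over matched
pairs; overall effectiveness is macro-IoU, the unweighted mean of the
per-FDI-label point-wise IoUs.  The challenge metrics (TLA, TSA, TIR
and their mean, the score) follow the public 3DTeethSeg conventions:
TLA is reported both as the raw mean tooth-size-normalized centroid
distance and as exp(-distance) so that, like the other metrics, higher
is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import f1_score

from .errors import ValidationError
from .scan import AnnotatedScan, BACKGROUND_INSTANCE

#: normalized-distance penalty for annotated teeth with no prediction
MISSING_TOOTH_PENALTY = 5.0
#: "closely predicted" threshold for the identification rate
TIR_DISTANCE_THRESHOLD = 0.5


@dataclass
class MatchResult:
    pairs: List[Tuple[int, int, float]]    # (annotated id, predicted id, IoU)
    unmatched_annotated: List[int]         # false negatives
    unmatched_predicted: List[int]         # false positives

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_annotated)

    @property
    def fp(self) -> int:
        return len(self.unmatched_predicted)


@dataclass
class MetricReport:
    f1: float
    tooth_dice: Optional[float]
    label_macro_f1: Optional[float]
    macro_iou: float
    tla_raw: float
    tla: float
    tsa: float
    tir: float                 # percentage, 0-100
    score: float
    counts: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, object]:
        return {
            "f1": self.f1, "tooth_dice": self.tooth_dice,
            "label_macro_f1": self.label_macro_f1,
            "macro_iou": self.macro_iou, "tla_raw": self.tla_raw,
            "tla": self.tla, "tsa": self.tsa, "tir": self.tir,
            "score": self.score, "counts": dict(self.counts),
        }


def _instance_sets(ids: np.ndarray) -> Dict[int, np.ndarray]:
    return {int(i): np.flatnonzero(ids == i)
            for i in np.unique(ids) if i != BACKGROUND_INSTANCE}


def match_teeth(gt: AnnotatedScan, pred_vertex_instance: np.ndarray,
                iou_threshold: float = 0.5) -> MatchResult:
    """One-to-one matching of annotated and predicted teeth.

    The assignment maximizes total IoU (Hungarian algorithm); pairs
    below the threshold are discarded to false positives/negatives.
    The threshold is inclusive: IoU exactly 0.5 counts as matched.
    """
    pred_vertex_instance = np.asarray(pred_vertex_instance, dtype=np.int64)
    if len(pred_vertex_instance) != len(gt.points):
        raise ValidationError("prediction and scan vertex counts differ")
    gt_sets = _instance_sets(gt.vertex_instance)
    pred_sets = _instance_sets(pred_vertex_instance)
    gt_ids, pred_ids = sorted(gt_sets), sorted(pred_sets)
    if not gt_ids or not pred_ids:
        return MatchResult([], list(gt_ids), list(pred_ids))

    iou = np.zeros((len(gt_ids), len(pred_ids)))
    for a, gid in enumerate(gt_ids):
        g = set(gt_sets[gid].tolist())
        for b, pid in enumerate(pred_ids):
            p = set(pred_sets[pid].tolist())
            inter = len(g & p)
            if inter:
                iou[a, b] = inter / len(g | p)
    rows, cols = linear_sum_assignment(-iou)
    pairs, matched_gt, matched_pred = [], set(), set()
    for a, b in zip(rows, cols):
        if iou[a, b] >= iou_threshold:
            pairs.append((gt_ids[a], pred_ids[b], float(iou[a, b])))
            matched_gt.add(gt_ids[a])
            matched_pred.add(pred_ids[b])
    return MatchResult(
        pairs,
        [g for g in gt_ids if g not in matched_gt],
        [p for p in pred_ids if p not in matched_pred],
    )


def detection_f1(match: MatchResult) -> float:
    """2TP / (2TP + FP + FN); 1.0 for the empty-vs-empty edge case."""
    denominator = 2 * match.tp + match.fp + match.fn
    if denominator == 0:
        warnings.warn("no annotated or predicted teeth; detection F1 = 1")
        return 1.0
    return 2.0 * match.tp / denominator


def tooth_dice(gt: AnnotatedScan, pred_vertex_instance: np.ndarray,
               match: MatchResult) -> Optional[float]:
    """Mean point-wise Dice over matched pairs; None without matches."""
    if not match.pairs:
        return None
    pred_vertex_instance = np.asarray(pred_vertex_instance, dtype=np.int64)
    dices = []
    for gid, pid, _ in match.pairs:
        g = gt.vertex_instance == gid
        p = pred_vertex_instance == pid
        dices.append(2.0 * float((g & p).sum())
                     / float(g.sum() + p.sum()))
    return float(np.mean(dices))


def label_macro_f1(gt_labels: Sequence[int], pred_labels: Sequence[int],
                   ) -> Optional[float]:
    """Macro-F1 of predicted vs annotated FDI labels over matched teeth.

    Unweighted mean over the classes present in the annotations; None
    when there are no matched pairs.
    """
    gt_labels = list(gt_labels)
    pred_labels = list(pred_labels)
    if len(gt_labels) != len(pred_labels):
        raise ValidationError("label lists must have equal length")
    if not gt_labels:
        return None
    classes = sorted(set(gt_labels))
    return float(f1_score(gt_labels, pred_labels, labels=classes,
                          average="macro", zero_division=0))


def macro_iou(gt: AnnotatedScan, pred_vertex_fdi: np.ndarray) -> float:
    """Unweighted mean over FDI labels of the point-wise label IoU.

    Labels present in either the annotation or the prediction
    contribute; labels absent from both are excluded.
    """
    pred_vertex_fdi = np.asarray(pred_vertex_fdi, dtype=np.int64)
    if len(pred_vertex_fdi) != len(gt.points):
        raise ValidationError("prediction and scan vertex counts differ")
    labels = sorted(set(np.unique(gt.vertex_fdi))
                    | set(np.unique(pred_vertex_fdi)))
    labels = [l for l in labels if l != 0]
    if not labels:
        warnings.warn("no labelled vertices on either side; macro-IoU = 1")
        return 1.0
    ious = []
    for label in labels:
        g = gt.vertex_fdi == label
        p = pred_vertex_fdi == label
        union = float((g | p).sum())
        ious.append(float((g & p).sum()) / union if union else 0.0)
    return float(np.mean(ious))


def _tooth_size(points: np.ndarray) -> float:
    """Diagonal of the axis-aligned bounding box (mm)."""
    return float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))


def challenge_metrics(gt: AnnotatedScan,
                      pred_vertex_instance: np.ndarray,
                      pred_instance_labels: Dict[int, int],
                      pred_instance_centroids: Optional[
                          Dict[int, np.ndarray]] = None,
                      ) -> Tuple[float, float, float, float, float]:
    """TLA (raw and exp-transformed), TSA, TIR and their mean score.

    tla_raw: mean over annotated teeth of the Euclidean distance from
    the annotated centroid to the closest predicted centroid, divided
    by the annotated tooth's size (bounding-box diagonal), with a fixed
    penalty when nothing was predicted.  tla = exp(-tla_raw).  tsa: F1
    over the binary tooth-vs-background vertex partition.  tir: the
    percentage of annotated teeth whose closest predicted tooth lies
    within normalized distance 0.5 and carries the same FDI label.
    score = (tla + tsa + tir/100) / 3.
    """
    pred_vertex_instance = np.asarray(pred_vertex_instance, dtype=np.int64)
    if len(pred_vertex_instance) != len(gt.points):
        raise ValidationError("prediction and scan vertex counts differ")
    pred_ids = sorted(_instance_sets(pred_vertex_instance))
    if pred_instance_centroids is None:
        pred_instance_centroids = {
            pid: gt.points[pred_vertex_instance == pid].mean(axis=0)
            for pid in pred_ids}
    centroid_matrix = (np.array([pred_instance_centroids[p]
                                 for p in pred_ids])
                       if pred_ids else np.zeros((0, 3)))

    gt_ids = gt.instance_ids()
    normalized, identified = [], []
    for gid in gt_ids:
        pts = gt.points[gt.vertex_instance == gid]
        size = _tooth_size(pts)
        if not pred_ids:
            normalized.append(MISSING_TOOTH_PENALTY)
            identified.append(False)
            continue
        distances = np.linalg.norm(centroid_matrix - pts.mean(axis=0),
                                   axis=1)
        closest = int(np.argmin(distances))
        norm_dist = float(distances[closest]) / size if size > 0 else 0.0
        normalized.append(norm_dist)
        identified.append(
            norm_dist < TIR_DISTANCE_THRESHOLD
            and pred_instance_labels.get(pred_ids[closest])
            == gt.label_of_instance(gid))

    if gt_ids:
        tla_raw = float(np.mean(normalized))
        tir = 100.0 * float(np.mean(identified))
    else:
        warnings.warn("no annotated teeth; TLA/TIR take perfect values")
        tla_raw, tir = 0.0, 100.0
    tla = float(np.exp(-tla_raw))

    gt_tooth = gt.vertex_instance != BACKGROUND_INSTANCE
    pred_tooth = pred_vertex_instance != BACKGROUND_INSTANCE
    tp = float((gt_tooth & pred_tooth).sum())
    fp = float((~gt_tooth & pred_tooth).sum())
    fn = float((gt_tooth & ~pred_tooth).sum())
    if tp + fp + fn == 0:
        tsa = 1.0
    else:
        tsa = 2.0 * tp / (2.0 * tp + fp + fn)

    score = (tla + tsa + tir / 100.0) / 3.0
    return tla_raw, tla, tsa, tir, score


def evaluate_scan(gt: AnnotatedScan,
                  pred_vertex_instance: np.ndarray,
                  pred_instance_labels: Dict[int, int],
                  pred_instance_centroids: Optional[
                      Dict[int, np.ndarray]] = None,
                  ) -> MetricReport:
    """All metrics for one scan in a single report."""
    match = match_teeth(gt, pred_vertex_instance)
    gt_matched = [gt.label_of_instance(g) for g, _, _ in match.pairs]
    pred_matched = [pred_instance_labels.get(p, 0)
                    for _, p, _ in match.pairs]
    wrong = sum(1 for g, p in zip(gt_matched, pred_matched) if g != p)

    pred_vertex_fdi = np.zeros(len(gt.points), dtype=np.int64)
    for pid, label in pred_instance_labels.items():
        pred_vertex_fdi[np.asarray(pred_vertex_instance) == pid] = label

    tla_raw, tla, tsa, tir, score = challenge_metrics(
        gt, pred_vertex_instance, pred_instance_labels,
        pred_instance_centroids)
    return MetricReport(
        f1=detection_f1(match),
        tooth_dice=tooth_dice(gt, pred_vertex_instance, match),
        label_macro_f1=label_macro_f1(gt_matched, pred_matched),
        macro_iou=macro_iou(gt, pred_vertex_fdi),
        tla_raw=tla_raw, tla=tla, tsa=tsa, tir=tir, score=score,
        counts={"tp": match.tp, "fp": match.fp, "fn": match.fn,
                "wrong_label": wrong},
    )
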