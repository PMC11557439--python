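"""Segmentation overlap metrics, multi-label classification report, volumetry.

Dice = 2|A∩B| / (|A|+|B|) and IoU (Jaccard) = |A∩B| / |A∪B| score mask
overlap; both are defined as 1.0 when prediction and reference are both
empty (correctly predicting "no hemorrhage" is a correct prediction).
Micro-averaged classification metrics pool the per-label decisions of
all five subtypes before counting.  Hematoma volume is foreground voxel
count times voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .image_io import SUBTYPE_NAMES, CTSeries, LabelMask, SubtypeLabels


@dataclass(frozen=True)
class SegScore:
    dice: float
    iou: float


@dataclass(frozen=True)
class MultiLabelReport:
    subset_accuracy: float
    per_label_mean_accuracy: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    micro_auc: Optional[float]  # None when pooled truths are single-class

    def to_dict(self) -> dict:
        return {
            "subset_accuracy": self.subset_accuracy,
            "per_label_mean_accuracy": self.per_label_mean_accuracy,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "micro_auc": self.micro_auc,
        }


def _binary_pair(a, b):
    a = a.binary() if isinstance(a, LabelMask) else (np.asarray(a) > 0)
    b = b.binary() if isinstance(b, LabelMask) else (np.asarray(b) > 0)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a.astype(bool), b.astype(bool)


def dice_score(a, b) -> float:
    a, b = _binary_pair(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou_score(a, b) -> float:
    a, b = _binary_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def seg_score(a, b) -> SegScore:
    return SegScore(dice=dice_score(a, b), iou=iou_score(a, b))


def hematoma_volume_ml(masks: Sequence[LabelMask], series: CTSeries) -> float:
    """Total foreground volume in millilitres (mm^3 / 1000)."""
    masks = list(masks)
    if len(masks) != len(series):
        raise ValueError("need one mask per slice")
    voxels = sum(int(m.binary().sum()) for m in masks)
    return voxels * series.voxel_volume_mm3() / 1000.0


def multilabel_report(
    probs: np.ndarray, truths: np.ndarray, threshold: float = 0.5
) -> MultiLabelReport:
    """Micro metrics over the pooled n x 5 per-label decisions."""
    probs = np.asarray(probs, dtype=float)
    truths = np.asarray(truths).astype(bool)
    if probs.ndim != 2 or probs.shape != truths.shape:
        raise ValueError("probs and truths must be equal-shaped n x k arrays")
    if probs.shape[0] < 1:
        raise ValueError("need at least one sample")
    preds = probs >= threshold

    subset_acc = float(np.all(preds == truths, axis=1).mean())
    per_label_acc = float((preds == truths).mean())

    t, p = truths.ravel(), preds.ravel()
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0

    pooled = probs.ravel()
    if t.all() or not t.any():
        auc = None
    else:
        auc = float(roc_auc_score(t, pooled))
    return MultiLabelReport(
        subset_accuracy=subset_acc,
        per_label_mean_accuracy=per_label_acc,
        micro_precision=prec,
        micro_recall=rec,
        micro_f1=f1,
        micro_auc=auc,
    )


def per_subtype_seg_scores(
    pred_masks: Sequence[LabelMask],
    gt_masks: Sequence[LabelMask],
    labels: Sequence[SubtypeLabels],
) -> Dict[str, List[SegScore]]:
    """Bucket per-slice binary-overlap scores by ground-truth subtype.

    A slice whose ground truth carries several subtypes contributes its
    score to every one of them.
    """
    if not (len(pred_masks) == len(gt_masks) == len(labels)):
        raise ValueError("pred_masks, gt_masks and labels must be aligned")
    out: Dict[str, List[SegScore]] = {n: [] for n in SUBTYPE_NAMES}
    for pm, gm, lab in zip(pred_masks, gt_masks, labels):
        score = seg_score(pm, gm)
        for name in SUBTYPE_NAMES:
            if getattr(lab, name):
                out[name].append(score)
    return out
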