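"""Evaluation: change ground truth, voxelwise ROC/AUC, response-class metrics.

Ground-truth growth/reduction masks come from subtracting the baseline
enhancing-tumor segmentation from the follow-up one.  The two-class ROC
scores growth voxels by the map value and reduction voxels by the negated
map value; the micro-average pools both classes' (score, label) pairs.  The
response-class metrics are one-vs-all sensitivity / specificity / accuracy
per class with a micro-average over the pooled confusion counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .change_analysis import RANO_CLASSES
from .volume_io import ValidationError, Volume

log = logging.getLogger("longimap")


@dataclass
class ChangeGroundTruth:
    growth_mask: np.ndarray
    reduction_mask: np.ndarray
    evaluation_mask: np.ndarray


@dataclass
class RocResult:
    auc_growth: Optional[float]
    auc_reduction: Optional[float]
    auc_micro: Optional[float]
    curves: dict

    def to_dict(self):
        return {
            "auc_growth": self.auc_growth,
            "auc_reduction": self.auc_reduction,
            "auc_micro": self.auc_micro,
        }


@dataclass
class ClassMetrics:
    per_class: dict     # class -> {sensitivity, specificity, accuracy}
    micro: dict         # micro-average of the pooled confusion counts

    def to_dict(self):
        return {"per_class": self.per_class, "micro": self.micro}


def _values(x):
    return x.values if isinstance(x, Volume) else np.asarray(x)


def change_ground_truth(seg1, seg2, brain_mask=None) -> ChangeGroundTruth:
    """Growth = seg2 minus seg1; reduction = seg1 minus seg2 (voxelwise)."""
    s1 = _values(seg1) > 0.5
    s2 = _values(seg2) > 0.5
    if s1.shape != s2.shape:
        raise ValidationError("segmentations must share one shape")
    ev = np.ones(s1.shape, bool) if brain_mask is None else _values(brain_mask) > 0.5
    return ChangeGroundTruth(
        growth_mask=s2 & ~s1, reduction_mask=s1 & ~s2, evaluation_mask=ev)


def _auc_mann_whitney(scores_pos, scores_neg) -> float:
    """Exact tie-corrected AUC via midranks (the Mann-Whitney statistic)."""
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    ranks = rankdata(np.concatenate([scores_pos, scores_neg]))
    return float(
        (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _roc_curve(scores_pos, scores_neg):
    from sklearn.metrics import roc_curve as _sk_roc

    y = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    s = np.concatenate([scores_pos, scores_neg])
    fpr, tpr, _ = _sk_roc(y, s)
    return fpr.tolist(), tpr.tolist()


def roc_auc(change_map, gt: ChangeGroundTruth, with_curves=True) -> RocResult:
    """Two-class voxelwise ROC: growth and reduction, plus micro-average.

    For each class, positives are that class's voxels and negatives are all
    evaluation-mask voxels outside it.  An empty class yields None (undefined)
    rather than an error.
    """
    m = _values(change_map).astype(np.float64)
    pooled_pos, pooled_neg = [], []
    aucs = {}
    curves = {}
    for name, mask, scores in (
        ("growth", gt.growth_mask, m),
        ("reduction", gt.reduction_mask, -m),
    ):
        pos_mask = mask & gt.evaluation_mask
        neg_mask = gt.evaluation_mask & ~mask
        if not pos_mask.any() or not neg_mask.any():
            aucs[name] = None
            continue
        sp, sn = scores[pos_mask], scores[neg_mask]
        aucs[name] = _auc_mann_whitney(sp, sn)
        pooled_pos.append(sp)
        pooled_neg.append(sn)
        if with_curves:
            curves[name] = _roc_curve(sp, sn)
    if pooled_pos:
        sp = np.concatenate(pooled_pos)
        sn = np.concatenate(pooled_neg)
        micro = _auc_mann_whitney(sp, sn)
        if with_curves:
            curves["micro"] = _roc_curve(sp, sn)
    else:
        micro = None
    return RocResult(aucs.get("growth"), aucs.get("reduction"), micro, curves)


def rano_metrics(predicted, truth) -> ClassMetrics:
    """One-vs-all metrics per response class plus their micro-average.

    Undefined ratios (zero denominators) are reported as None and excluded
    from the micro-average pooling with a warning.
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValidationError("predicted and truth must have equal length")
    if len(truth) == 0:
        raise ValidationError("need at least one item")
    for c in predicted + truth:
        if c not in RANO_CLASSES:
            raise ValidationError(f"unknown class: {c}")
    n = len(truth)
    pred = np.asarray(predicted)
    true = np.asarray(truth)

    def ratio(num, den):
        return float(num) / den if den > 0 else None

    per_class = {}
    totals = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for c in RANO_CLASSES:
        tp = int(np.sum((pred == c) & (true == c)))
        tn = int(np.sum((pred != c) & (true != c)))
        fp = int(np.sum((pred == c) & (true != c)))
        fn = int(np.sum((pred != c) & (true == c)))
        assert tp + tn + fp + fn == n
        per_class[c] = {
            "sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "accuracy": (tp + tn) / n,
        }
        if per_class[c]["sensitivity"] is None or per_class[c]["specificity"] is None:
            log.warning("class %s has undefined metrics; excluded from micro", c)
            continue
        for k, v in zip(("tp", "tn", "fp", "fn"), (tp, tn, fp, fn)):
            totals[k] += v
    tp, tn, fp, fn = totals["tp"], totals["tn"], totals["fp"], totals["fn"]
    micro = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
    }
    return ClassMetrics(per_class=per_class, micro=micro)
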