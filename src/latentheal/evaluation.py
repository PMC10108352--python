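"""Segmentation and detection metrics.

Includes the best-achievable DICE score: the maximum DICE over a shared
residual-binarization threshold searched on the pooled test set — an upper
bound on segmentation performance that does not depend on choosing an
operating point.  Curve metrics (AUPRC, AUROC, FPR at fixed TPR) are
computed with scikit-learn.

Conventions: DICE of two empty masks is 1 (perfect agreement).  For the
FPR-at-TPR metrics the *in-distribution* examples are the positives, so
FPR80 is the fraction of anomalous examples accepted at the threshold
where 80% of in-distribution examples are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

__all__ = [
    "dice",
    "best_dice",
    "auprc",
    "auroc",
    "fpr_at_tpr",
    "EvalReport",
    "evaluate_segmentation",
]

MAX_EXACT_THRESHOLDS = 10_000
N_QUANTILE_THRESHOLDS = 1024


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """2|A∩B| / (|A| + |B|); both-empty -> 1."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / denom)


def best_dice(residuals, gt_masks, thresholds: np.ndarray | None = None) -> tuple[float, float]:
    """Greedy search for the single residual threshold maximizing DICE.

    `residuals` and `gt_masks` are same-shaped arrays or lists of arrays;
    the threshold is global over the pooled set.  Candidate thresholds
    default to all unique residual values when there are at most 10^4 of
    them, else 1,024 quantile-spaced values.  Returns (best_dice,
    best_threshold), where a pixel is predicted anomalous when its
    residual is strictly above the threshold.
    """
    if isinstance(residuals, np.ndarray):
        residuals = [residuals]
    if isinstance(gt_masks, np.ndarray):
        gt_masks = [gt_masks]
    r = np.concatenate([np.asarray(x, dtype=np.float64).ravel() for x in residuals])
    g = np.concatenate([np.asarray(x).astype(bool).ravel() for x in gt_masks])
    if r.shape != g.shape:
        raise ValueError("residuals and ground-truth masks cover different pixel counts")
    if thresholds is None:
        uniq = np.unique(r)
        if uniq.size <= MAX_EXACT_THRESHOLDS:
            # midpoint below each unique value makes `> t` select exactly
            # the pixels at or above that value
            lows = np.concatenate([[uniq[0] - 1.0], uniq[:-1]])
            thresholds = np.concatenate([(lows + uniq) / 2.0, [uniq[-1]]])
        else:
            qs = np.linspace(0.0, 1.0, N_QUANTILE_THRESHOLDS)
            thresholds = np.unique(np.quantile(r, qs))
    thresholds = np.asarray(thresholds, dtype=np.float64)
    # vectorized sweep: sort residuals once, count positives above threshold
    order = np.argsort(r, kind="stable")
    r_sorted = r[order]
    g_sorted = g[order].astype(np.int64)
    cum_gt = np.concatenate([[0], np.cumsum(g_sorted)])
    n = r.size
    total_gt = int(g.sum())
    firsts = np.searchsorted(r_sorted, thresholds, side="right")
    n_pred = n - firsts
    tp = total_gt - cum_gt[firsts]
    denom = n_pred + total_gt
    dices = np.where(denom > 0, 2.0 * tp / np.maximum(denom, 1), 1.0)
    i = int(np.argmax(dices))
    return float(dices[i]), float(thresholds[i])


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined: labels contain a single class")
    return labels


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (label 1 = positive)."""
    labels = _check_labels(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64).ravel()))


def auroc(scores, labels) -> float:
    """Area under the ROC curve (label 1 = positive)."""
    labels = _check_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64).ravel()))


def fpr_at_tpr(scores, labels, tpr_level: float) -> float:
    """FPR at the first threshold reaching the requested TPR.

    `labels`: 1 = in-distribution (positive), 0 = anomalous; higher score
    = more in-distribution.
    """
    if not 0.0 < tpr_level <= 1.0:
        raise ValueError(f"tpr_level must be in (0,1], got {tpr_level}")
    labels = _check_labels(labels)
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=np.float64).ravel())
    idx = int(np.searchsorted(tpr, tpr_level, side="left"))
    idx = min(idx, len(fpr) - 1)
    return float(fpr[idx])


@dataclass
class EvalReport:
    best_dice: float
    best_threshold: float
    auprc: float
    auroc: float | None = None
    fpr80: float | None = None
    fpr95: float | None = None
    fpr99: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def evaluate_segmentation(residuals, gt_masks) -> EvalReport:
    """Pixel-level report: best-achievable DICE and AUPRC over pooled pixels."""
    bd, bt = best_dice(residuals, gt_masks)
    r = np.concatenate([np.asarray(x, dtype=np.float64).ravel() for x in residuals])
    g = np.concatenate([np.asarray(x).astype(bool).ravel() for x in gt_masks]).astype(int)
    return EvalReport(best_dice=bd, best_threshold=bt, auprc=float(average_precision_score(g, r)))
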