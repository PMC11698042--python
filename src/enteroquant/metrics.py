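"""Segmentation evaluation: instance matching / F1-over-IoU, count error,
semantic mask IoU, Adapted Rand error and split/merge variation of information.

Instance matching follows the convention of star-convex segmentation
benchmarks: a one-to-one assignment between ground-truth and predicted
objects that maximises total IoU (Hungarian algorithm), after which a match
counts as a true positive when its IoU reaches the threshold τ.  Because the
assignment is computed once and thresholds are applied to it, the F1 curve is
non-increasing in τ by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment

from .imgio import LabelMap

__all__ = [
    "MatchResult",
    "PartitionMetrics",
    "match_instances",
    "f1_curve",
    "percent_count_error",
    "mask_iou",
    "partition_metrics",
]


@dataclass(frozen=True)
class MatchResult:
    tau: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    mean_matched_iou: float


@dataclass(frozen=True)
class PartitionMetrics:
    adapted_rand_error: float
    voi_split: float  # H(pred | gt), bits: fragmentation of gt objects
    voi_merge: float  # H(gt | pred), bits: merging of gt objects


def _as_labels(x: LabelMap | np.ndarray) -> np.ndarray:
    arr = x.labels if isinstance(x, LabelMap) else np.asarray(x)
    if arr.ndim != 2:
        raise ValueError("label maps must be 2D")
    return arr


def _contingency(gt: np.ndarray, pred: np.ndarray) -> sparse.csr_matrix:
    """Pixel-count contingency table of (gt label, pred label)."""
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    n_gt = int(gt.max()) + 1
    n_pred = int(pred.max()) + 1
    data = np.ones(gt.size, dtype=np.int64)
    return sparse.coo_matrix(
        (data, (gt.ravel(), pred.ravel())), shape=(n_gt, n_pred)
    ).tocsr()


def _matched_ious(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Optimal one-to-one assignment IoUs plus object counts.

    Returns the IoU values of assigned (gt, pred) pairs with positive overlap,
    and the number of gt / pred objects.
    """
    cont = _contingency(gt, pred)
    gt_areas = np.asarray(cont.sum(axis=1)).ravel()
    pred_areas = np.asarray(cont.sum(axis=0)).ravel()
    inter = cont[1:, 1:].tocoo()  # drop background row/col
    n_gt = int(np.sum(gt_areas[1:] > 0))
    n_pred = int(np.sum(pred_areas[1:] > 0))
    if inter.nnz == 0:
        return np.empty(0), n_gt, n_pred
    iou = sparse.coo_matrix(
        (
            inter.data / (gt_areas[1:][inter.row] + pred_areas[1:][inter.col] - inter.data),
            (inter.row, inter.col),
        ),
        shape=inter.shape,
    )
    dense = iou.toarray()
    rows, cols = linear_sum_assignment(dense, maximize=True)
    vals = dense[rows, cols]
    return vals[vals > 0], n_gt, n_pred


def _result_at(ious: np.ndarray, n_gt: int, n_pred: int, tau: float) -> MatchResult:
    tp = int(np.sum(ious >= tau))
    fp = n_pred - tp
    fn = n_gt - tp
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_gt if n_gt else 0.0
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    mean_iou = float(np.mean(ious[ious >= tau])) if tp else 0.0
    return MatchResult(tau, tp, fp, fn, precision, recall, f1, mean_iou)


def match_instances(gt: LabelMap | np.ndarray, pred: LabelMap | np.ndarray, tau: float = 0.5) -> MatchResult:
    """Instance detection scores at one IoU threshold ``tau`` in (0, 1)."""
    if not (0 < tau < 1):
        raise ValueError("tau must lie strictly between 0 and 1")
    ious, n_gt, n_pred = _matched_ious(_as_labels(gt), _as_labels(pred))
    return _result_at(ious, n_gt, n_pred, tau)


def f1_curve(
    gt: LabelMap | np.ndarray,
    pred: LabelMap | np.ndarray,
    taus: np.ndarray | None = None,
) -> list[MatchResult]:
    """Sweep τ over the fixed optimal assignment; F1 is non-increasing in τ."""
    if taus is None:
        taus = np.arange(0.10, 0.901, 0.05)
    ious, n_gt, n_pred = _matched_ious(_as_labels(gt), _as_labels(pred))
    return [_result_at(ious, n_gt, n_pred, float(t)) for t in taus]


def percent_count_error(n_gt: int, n_pred: int) -> float:
    """Percentage cell count error, 100·|n_gt − n_pred| / n_gt."""
    if n_gt <= 0:
        raise ValueError("n_gt must be positive")
    return 100.0 * abs(n_gt - n_pred) / n_gt


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Semantic IoU of two binary masks; both empty → 1, exactly one empty → 0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def partition_metrics(gt: LabelMap | np.ndarray, pred: LabelMap | np.ndarray) -> PartitionMetrics:
    """Adapted Rand error and VOI split/merge over gt-foreground pixels.

    Background pixels of the ground truth are excluded; predicted background
    inside the gt foreground is treated as one additional segment.  VOI uses
    base-2 logarithms: ``voi_split = H(pred | gt)`` grows when gt objects are
    fragmented by the prediction (pred carries extra detail), ``voi_merge =
    H(gt | pred)`` grows when the prediction merges gt objects (pred loses
    detail).
    """
    gt = _as_labels(gt)
    pred = _as_labels(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    fg = gt > 0
    if not fg.any():
        raise ValueError("ground truth is entirely background")
    g = gt[fg].astype(np.int64)
    p = pred[fg].astype(np.int64)
    p = np.where(p == 0, p.max() + 1, p)  # pred background = its own segment

    cont = _contingency(g[None], p[None]).astype(np.float64)
    n = cont.sum()
    pij = cont.tocoo()
    a_counts = np.asarray(cont.sum(axis=1)).ravel()  # gt marginals
    b_counts = np.asarray(cont.sum(axis=0)).ravel()  # pred marginals

    # Adapted Rand error: 1 − F-score of the pair-counting contingency
    # (distinct unordered pixel pairs, i.e. Σ n² − n counting).
    pairs_joint = np.sum(pij.data**2) - n
    pairs_gt = np.sum(a_counts**2) - n
    pairs_pred = np.sum(b_counts**2) - n
    if pairs_gt == 0 and pairs_pred == 0:
        are = 0.0  # single-pixel segments everywhere: identical partitions
    elif pairs_joint == 0:
        are = 1.0
    else:
        prec = pairs_joint / pairs_pred
        rec = pairs_joint / pairs_gt
        are = 1.0 - 2.0 * prec * rec / (prec + rec)

    # Conditional entropies in bits.
    a = a_counts / n
    b = b_counts / n
    joint = pij.data / n
    h_joint = -np.sum(joint * np.log2(joint))
    h_gt = -np.sum(a[a > 0] * np.log2(a[a > 0]))
    h_pred = -np.sum(b[b > 0] * np.log2(b[b > 0]))
    voi_split = h_joint - h_gt  # H(pred | gt): fragmentation of gt objects
    voi_merge = h_joint - h_pred  # H(gt | pred): merging of gt objects
    return PartitionMetrics(float(max(are, 0.0)), float(max(voi_split, 0.0)), float(max(voi_merge, 0.0)))
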