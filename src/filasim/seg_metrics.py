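"""Skeleton-IoU based segmentation scoring.

Pixel IoU over-penalizes one-pixel lateral shifts of objects that are only
a few pixels wide.  The skeleton IoU of two instance masks is

    SKIoU = 2 · |S(M_pred ∩ M_gt)| / (|S(M_pred)| + |S(M_gt)|)

where S is morphological thinning to a one-pixel-wide skeleton and the
intersection is taken BEFORE skeletonization, so a laterally shifted but
overlapping pair still shares a long intersection skeleton.

Two aggregation protocols coexist deliberately:

* ``mean_skiou`` — per ground-truth instance, the best-matching prediction's
  SKIoU (non-exclusive; a prediction may serve several GT instances), with
  0 for unmatched GT.  Misses are penalized, false positives are not.
* ``ap_f1_scores`` — greedy one-to-one matching at SKIoU thresholds
  0.50 … 0.95 (step 0.05); AP@τ = TP/(TP+FP+FN) (the confidence-free
  convention of the cell-segmentation community), F1@τ = 2TP/(2TP+FP+FN).

Dataset-level scores are macro-averages: per image first, then across
images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .dataset_io import InstanceMaskStack

__all__ = [
    "MatchTable",
    "SegScores",
    "AP_THRESHOLDS",
    "skeletonize",
    "skiou",
    "mean_skiou",
    "match_instances",
    "ap_f1_scores",
    "evaluate_dataset",
]

AP_THRESHOLDS: tuple[float, ...] = tuple(round(0.50 + 0.05 * k, 2) for k in range(10))


@dataclass
class MatchTable:
    """Greedy one-to-one matches at one threshold."""

    threshold: float
    pairs: list[tuple[int, int | None, float]]  # (gt index, pred index, skiou)

    @property
    def n_matched(self) -> int:
        return sum(1 for _, p, _ in self.pairs if p is not None)


@dataclass
class SegScores:
    """Per-image scores; fields are None when undefined (no GT instances
    and, for AP/F1, no predictions either — nothing to score)."""

    mean_skiou: float | None
    ap: float | None
    f1_50: float | None
    f1_75: float | None
    per_threshold: dict[float, dict[str, float]] = field(default_factory=dict)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide morphological thinning (empty in → empty out)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _skimage_skeletonize(mask)


def skiou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Skeleton IoU of one predicted and one ground-truth mask.

    Both-empty pairs are defined as 0; the value is capped at 1.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    s_pred = int(skeletonize(pred).sum())
    s_gt = int(skeletonize(gt).sum())
    if s_pred + s_gt == 0:
        return 0.0
    s_inter = int(skeletonize(pred & gt).sum())
    return min(1.0, 2.0 * s_inter / (s_pred + s_gt))


def _skiou_matrix(preds: InstanceMaskStack, gt: InstanceMaskStack) -> np.ndarray:
    if preds.shape != gt.shape:
        raise ValueError("prediction and ground-truth canvases differ")
    mat = np.zeros((len(gt), len(preds)))
    for g, gm in enumerate(gt):
        for p, pm in enumerate(preds):
            if (gm & pm).any():  # disjoint pairs score 0, skip the thinning
                mat[g, p] = skiou(pm, gm)
    return mat


def mean_skiou(preds: InstanceMaskStack, gt: InstanceMaskStack) -> float | None:
    """Per-GT best SKIoU (non-exclusive), averaged over GT instances.

    Empty ground truth is undefined and reported as None; empty predictions
    against nonempty ground truth score 0.
    """
    if len(gt) == 0:
        return None
    if len(preds) == 0:
        return 0.0
    mat = _skiou_matrix(preds, gt)
    return float(np.mean(np.max(mat, axis=1)))


def match_instances(preds: InstanceMaskStack, gt: InstanceMaskStack,
                    threshold: float,
                    skiou_matrix: np.ndarray | None = None) -> MatchTable:
    """Greedy one-to-one matching in descending SKIoU order.

    Pairs below ``threshold`` stay unmatched.  Ties are broken by the lower
    (gt index, pred index), which makes matching deterministic.
    """
    mat = _skiou_matrix(preds, gt) if skiou_matrix is None else skiou_matrix
    candidates = [(-mat[g, p], g, p)
                  for g in range(mat.shape[0]) for p in range(mat.shape[1])
                  if mat[g, p] >= threshold]
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    matched: dict[int, tuple[int, float]] = {}
    for neg, g, p in candidates:
        if g in used_g or p in used_p:
            continue
        used_g.add(g)
        used_p.add(p)
        matched[g] = (p, -neg)
    pairs = [(g, *(matched.get(g, (None, 0.0)))) for g in range(mat.shape[0])]
    return MatchTable(threshold=threshold, pairs=pairs)


def ap_f1_scores(preds: InstanceMaskStack, gt: InstanceMaskStack) -> SegScores:
    """Mean SKIoU, AP over the 10-threshold grid, and F1@0.50 / F1@0.75."""
    mat = _skiou_matrix(preds, gt)
    n_gt, n_pred = mat.shape
    if n_gt == 0 and n_pred == 0:
        return SegScores(mean_skiou=None, ap=None, f1_50=None, f1_75=None)
    per_threshold: dict[float, dict[str, float]] = {}
    ap_values = []
    f1_at: dict[float, float] = {}
    for tau in AP_THRESHOLDS:
        table = match_instances(preds, gt, tau, skiou_matrix=mat)
        tp = table.n_matched
        fp = n_pred - tp
        fn = n_gt - tp
        denom = tp + fp + fn
        ap_tau = tp / denom if denom > 0 else 0.0
        f1_tau = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        per_threshold[tau] = {"tp": tp, "fp": fp, "fn": fn, "ap": ap_tau, "f1": f1_tau}
        ap_values.append(ap_tau)
        f1_at[tau] = f1_tau
    ms = mean_skiou(preds, gt)
    return SegScores(mean_skiou=ms, ap=float(np.mean(ap_values)),
                     f1_50=f1_at[0.5], f1_75=f1_at[0.75],
                     per_threshold=per_threshold)


def evaluate_dataset(preds_list: list[InstanceMaskStack],
                     gts_list: list[InstanceMaskStack]) -> dict[str, float]:
    """Macro-average per-image scores; images with empty GT are excluded
    from the mean-SKIoU average (undefined there)."""
    if len(preds_list) != len(gts_list):
        raise ValueError("prediction and ground-truth lists differ in length")
    skious, aps, f50s, f75s = [], [], [], []
    for preds, gt in zip(preds_list, gts_list):
        scores = ap_f1_scores(preds, gt)
        if scores.mean_skiou is not None:
            skious.append(scores.mean_skiou)
        if scores.ap is not None:
            aps.append(scores.ap)
            f50s.append(scores.f1_50)
            f75s.append(scores.f1_75)
    return {
        "mean_skiou": float(np.mean(skious)) if skious else float("nan"),
        "ap": float(np.mean(aps)) if aps else float("nan"),
        "f1_50": float(np.mean(f50s)) if f50s else float("nan"),
        "f1_75": float(np.mean(f75s)) if f75s else float("nan"),
        "n_images": len(preds_list),
    }
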