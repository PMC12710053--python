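"""Segmentation evaluation metrics over predicted vs ground-truth label masks.

The predicted region ``M_p`` is the combined coat+radicle area; ``M_g`` its
ground truth. Besides Dice, IoU and FPR, pixel accuracy (PA) is implemented
exactly as defined here — intersection over ground truth, i.e. recall of the
foreground — which differs from the conventional all-pixel accuracy.
Component IoUs are computed for seed coat, radicle and background, and mIoU
is their unweighted mean. Ratios with an empty denominator are reported as
``None`` rather than 0, so averages are never silently inflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MaskPair:
    """Predicted and ground-truth {0,1,2} label rasters of equal shape."""

    pred: np.ndarray
    gt: np.ndarray

    def __post_init__(self) -> None:
        pred = np.asarray(self.pred)
        gt = np.asarray(self.gt)
        if pred.shape != gt.shape:
            raise ValueError("predicted and ground-truth masks must share a shape")
        for arr, name in ((pred, "pred"), (gt, "gt")):
            if not np.isin(arr, (0, 1, 2)).all():
                raise ValueError(f"{name} mask must be labelled 0/1/2")
        object.__setattr__(self, "pred", pred)
        object.__setattr__(self, "gt", gt)

    @classmethod
    def from_binary(cls, pred_coat, pred_radicle, gt_coat, gt_radicle) -> "MaskPair":
        from .io_core import masks_to_labels
        return cls(pred=masks_to_labels(pred_coat, pred_radicle),
                   gt=masks_to_labels(gt_coat, gt_radicle))


@dataclass(frozen=True)
class SegmentationScores:
    dice: float | None
    iou: float | None
    pa: float | None
    fpr: float | None
    iou_sc: float | None
    iou_rd: float | None
    iou_bg: float | None
    miou: float | None


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def _iou(a: np.ndarray, b: np.ndarray) -> float | None:
    return _ratio(int(np.logical_and(a, b).sum()), int(np.logical_or(a, b).sum()))


def segmentation_scores(pair: MaskPair) -> SegmentationScores:
    """Dice, IoU, PA, FPR and the component/mean IoUs for one mask pair."""
    m_p = pair.pred > 0
    m_g = pair.gt > 0
    inter = int(np.logical_and(m_p, m_g).sum())
    union = int(np.logical_or(m_p, m_g).sum())
    n_p, n_g = int(m_p.sum()), int(m_g.sum())
    m_bg = ~m_g

    dice = _ratio(2 * inter, n_p + n_g)
    iou = _ratio(inter, union)
    pa = _ratio(inter, n_g)
    fpr = _ratio(int(np.logical_and(m_p, ~m_g).sum()), int(m_bg.sum()))

    iou_sc = _iou(pair.pred == 1, pair.gt == 1)
    iou_rd = _iou(pair.pred == 2, pair.gt == 2)
    iou_bg = _iou(pair.pred == 0, pair.gt == 0)
    if None in (iou_sc, iou_rd, iou_bg):
        miou = None
    else:
        miou = (iou_sc + iou_rd + iou_bg) / 3.0
    return SegmentationScores(dice=dice, iou=iou, pa=pa, fpr=fpr,
                              iou_sc=iou_sc, iou_rd=iou_rd, iou_bg=iou_bg,
                              miou=miou)
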