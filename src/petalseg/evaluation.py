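"""Scoring predictions against ground truth.

Implements the standard COCO detection protocol for a single "petal"
category: per-image greedy matching of score-sorted detections to ground
truth at each IoU threshold, 101-point interpolated average precision, and
average recall at 100 detections per image, averaged over IoU thresholds
0.50:0.05:0.95.  Petal morphology is scored by per-region pixel areas
(converted to mm^2 through the physical pixel size) and the mean absolute
percentage error

    MAPE = (100 / n) * sum_i |E_i - G_i| / G_i

between estimated and ground-truth petal areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .backends import InstanceSet, SegmentInstance
from .io import LabelMask2D

__all__ = [
    "AreaMatch",
    "EvalReport",
    "iou",
    "ap_ar",
    "mape_area",
    "area_stats",
    "match_areas",
    "labels_to_instances",
]

COCO_IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)
_REC_THRS = np.linspace(0.0, 1.0, 101)


@dataclass
class AreaMatch:
    """Estimated vs ground-truth area of one petal (same units)."""

    est_area: float
    gt_area: float
    petal_index: int = 0

    def __post_init__(self) -> None:
        if not self.gt_area > 0:
            raise ValueError("gt_area must be positive")


@dataclass
class EvalReport:
    """AP/AR table plus optional area statistics."""

    ap: dict[float | str, float | None]
    ar: dict[float | str, float | None]
    mape_percent: float | None = None
    area_mean_mm2: float | None = None
    area_var_mm2: float | None = None
    n_images: int = 0
    n_gt: int = 0
    n_pred: int = 0

    def to_dict(self) -> dict:
        return {
            "ap": {str(k): v for k, v in self.ap.items()},
            "ar": {str(k): v for k, v in self.ar.items()},
            "mape_percent": self.mape_percent,
            "area_mean_mm2": self.area_mean_mm2,
            "area_var_mm2": self.area_var_mm2,
            "n_images": self.n_images,
            "n_gt": self.n_gt,
            "n_pred": self.n_pred,
        }


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary regions on the same raster."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("IoU of two empty regions defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def labels_to_instances(mask: LabelMask2D,
                        scores: dict[int, float] | None = None) -> InstanceSet:
    """View each labeled region of a label map as a scored instance."""
    instances = []
    flat = mask.labels.reshape(-1)
    order = np.argsort(flat, kind="stable")
    vals = flat[order]
    for lab in mask.ids():
        lo = np.searchsorted(vals, lab)
        hi = np.searchsorted(vals, lab, side="right")
        score = 1.0 if scores is None else float(scores.get(int(lab), 1.0))
        instances.append(SegmentInstance(np.sort(order[lo:hi]), mask.shape,
                                         score, int(lab)))
    return InstanceSet(instances, None, mask.index, mask.shape, disjoint=True)


def _iou_matrix(dets: list[SegmentInstance], gts: list[SegmentInstance]) -> np.ndarray:
    out = np.zeros((len(dets), len(gts)))
    for i, d in enumerate(dets):
        for j, g in enumerate(gts):
            inter = np.intersect1d(d.pixels, g.pixels, assume_unique=True).size
            union = d.area + g.area - inter
            out[i, j] = inter / union if union else 0.0
    return out


def ap_ar(preds: list[InstanceSet], gts: list[LabelMask2D],
          iou_thresholds: np.ndarray | None = None,
          max_dets: int = 100) -> EvalReport:
    """COCO-protocol AP/AR for scored instance predictions.

    ``preds[i]`` holds the slice-frame detections for image i and ``gts[i]``
    its ground-truth label map.  AP is the 101-point interpolated area under
    the precision-recall curve accumulated over all images; AR is the recall
    at ``max_dets`` detections per image.  Reported at IoU 0.50, 0.75 and as
    the mean over 0.50:0.05:0.95.  With no ground-truth instances anywhere,
    AP/AR are undefined and reported as None.
    """
    if len(preds) != len(gts):
        raise ValueError("preds and gts must be parallel lists")
    thrs = COCO_IOU_THRESHOLDS if iou_thresholds is None else np.asarray(iou_thresholds)
    T = len(thrs)
    all_scores: list[np.ndarray] = []
    all_matched: list[np.ndarray] = []  # (T, n_dets) bool per image
    npig = 0
    n_pred = 0
    for pset, gmask in zip(preds, gts):
        dets = sorted(pset.instances, key=lambda d: -d.score)[:max_dets]
        n_pred += len(pset.instances)
        gset = labels_to_instances(gmask).instances
        npig += len(gset)
        if not dets:
            continue
        ious = _iou_matrix(dets, gset)
        matched = np.zeros((T, len(dets)), dtype=bool)
        for t_i, t in enumerate(thrs):
            gt_taken = np.zeros(len(gset), dtype=bool)
            for d_i in range(len(dets)):
                best = min(t, 1.0 - 1e-10)
                m = -1
                for g_i in range(len(gset)):
                    if gt_taken[g_i]:
                        continue
                    if ious[d_i, g_i] < best:
                        continue
                    best = ious[d_i, g_i]
                    m = g_i
                if m >= 0:
                    gt_taken[m] = True
                    matched[t_i, d_i] = True
        all_scores.append(np.array([d.score for d in dets]))
        all_matched.append(matched)
    if npig == 0:
        none_tab = {0.5: None, 0.75: None, "mean": None}
        return EvalReport(dict(none_tab), dict(none_tab), n_images=len(gts),
                          n_gt=0, n_pred=n_pred)
    ap_t = np.zeros(T)
    ar_t = np.zeros(T)
    if all_scores:
        scores = np.concatenate(all_scores)
        matched = np.concatenate(all_matched, axis=1)
        order = np.argsort(-scores, kind="mergesort")
        matched = matched[:, order]
        for t_i in range(T):
            tps = np.cumsum(matched[t_i])
            fps = np.cumsum(~matched[t_i])
            rc = tps / npig
            pr = tps / np.maximum(tps + fps, 1e-12)
            ar_t[t_i] = rc[-1]
            # precision envelope (monotone non-increasing from the right)
            q = pr.copy()
            for i in range(len(q) - 1, 0, -1):
                q[i - 1] = max(q[i - 1], q[i])
            inds = np.searchsorted(rc, _REC_THRS, side="left")
            prec = np.zeros(len(_REC_THRS))
            ok = inds < len(q)
            prec[ok] = q[inds[ok]]
            ap_t[t_i] = prec.mean()

    def table(vals: np.ndarray) -> dict:
        out: dict = {}
        for key in (0.5, 0.75):
            idx = np.flatnonzero(np.isclose(thrs, key))
            out[key] = float(vals[idx[0]]) if idx.size else None
        out["mean"] = float(vals.mean())
        return out

    return EvalReport(table(ap_t), table(ar_t), n_images=len(gts),
                      n_gt=npig, n_pred=n_pred)


def mape_area(matches: list[AreaMatch]) -> float:
    """Mean absolute percentage error of estimated vs ground-truth areas."""
    if not matches:
        raise ValueError("need at least one matched petal")
    errs = []
    for m in matches:
        if m.gt_area == 0:
            raise ValueError("ground-truth area must be non-zero")
        errs.append(abs(m.est_area - m.gt_area) / m.gt_area)
    return float(100.0 * np.mean(errs))


def match_areas(pred: LabelMask2D, gt: LabelMask2D, min_iou: float = 0.5) -> list[AreaMatch]:
    """Greedy best-IoU pairing of predicted and GT regions for area scoring.

    The study protocol matched regions manually; greedy IoU >= ``min_iou``
    matching reproduces it automatically when the segmentation is reasonable.
    """
    from .integrate3d import match_adjacent

    mapping = match_adjacent(pred, gt, iou_threshold=min_iou)
    out = []
    for i, (p_lab, g_lab) in enumerate(sorted(mapping.items())):
        out.append(AreaMatch(float((pred.labels == p_lab).sum()),
                             float((gt.labels == g_lab).sum()), i))
    return out


def area_stats(labels: list[LabelMask2D], pixel_size_um: float):
    """Per-petal areas in mm^2 plus their sample mean and variance.

    Every labeled region on every slice counts as one petal observation, as
    in per-image area scoring of 2D segmentations.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    px_mm2 = (pixel_size_um ** 2) / 1e6  # um^2 -> mm^2
    areas = []
    for m in labels:
        ids, counts = np.unique(m.labels[m.labels > 0], return_counts=True)
        areas.extend(counts * px_mm2)
    if not areas:
        raise ValueError("no petals found")
    areas = np.asarray(areas, dtype=np.float64)
    var = float(areas.var(ddof=1)) if areas.size > 1 else float("nan")
    return areas, float(areas.mean()), var
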