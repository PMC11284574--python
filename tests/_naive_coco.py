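"""Independent plain-loop implementation of the COCO detection protocol.

Deliberately kept separate from, and structurally unlike, the vectorized
evaluator in ``petalseg.evaluation``: masks are dense boolean grids, matching
and precision-recall accumulation are explicit Python loops, and the
101-point interpolation is computed by its defining maximum rather than an
envelope + searchsorted.  Serves as the cross-check oracle for AP/AR.
"""

from __future__ import annotations

import numpy as np


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    return inter / union if union else 0.0


def naive_ap_ar(preds, gts, thr: float, max_dets: int = 100):
    """AP and AR at one IoU threshold.

    ``preds[i]`` is a list of (mask, score) for image i, ``gts[i]`` a list of
    masks.  Returns (ap, ar).
    """
    total_gt = sum(len(g) for g in gts)
    records = []  # (score, is_tp) in image order, score-sorted within image
    for det_list, gt_list in zip(preds, gts):
        order = sorted(range(len(det_list)), key=lambda k: -det_list[k][1])
        order = order[:max_dets]
        taken = [False] * len(gt_list)
        for k in order:
            mask, score = det_list[k]
            best = min(thr, 1.0 - 1e-10)
            match = -1
            for g, gmask in enumerate(gt_list):
                if taken[g]:
                    continue
                v = mask_iou(mask, gmask)
                if v < best:
                    continue
                best = v
                match = g
            if match >= 0:
                taken[match] = True
            records.append((score, match >= 0))
    if total_gt == 0:
        return None, None
    # global stable sort by descending score, preserving image order on ties
    records = [records[i] for i in sorted(range(len(records)),
                                          key=lambda i: -records[i][0])]
    tp = 0
    fp = 0
    points = []  # (recall, precision) after each detection
    for _, is_tp in records:
        if is_tp:
            tp += 1
        else:
            fp += 1
        points.append((tp / total_gt, tp / (tp + fp)))
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        best_p = 0.0
        for rec, prec in points:
            if rec >= r and prec > best_p:
                best_p = prec
        ap += best_p / 101.0
    ar = tp / total_gt
    return ap, ar
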