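"""Stacking per-slice label maps into a consistent 3D petal labeling.

Each slice is labeled independently by the 2D integration, so the same petal
carries unrelated label ids on different slices.  Consistency is restored
sequentially from the top slice down: every label of slice k+1 is matched to
the label of slice k with which it has the highest IoU, provided that IoU is
at least the threshold (0.8 by default) and the matching stays one-to-one.
Matched labels inherit the partner's global id; unmatched labels open a new
global id.  A global id that disappears on some slice is never revived, so
each petal's slice support is a contiguous interval by construction.
"""

from __future__ import annotations

import numpy as np

from .io import LabelMask2D, PetalLabelVolume

__all__ = ["match_adjacent", "propagate_labels"]


def _label_contingency(upper: np.ndarray, lower: np.ndarray):
    """Intersection counts and areas for all co-occurring label pairs."""
    up = upper.reshape(-1).astype(np.int64)
    lo = lower.reshape(-1).astype(np.int64)
    area_u = np.bincount(up)
    area_l = np.bincount(lo)
    both = (up > 0) & (lo > 0)
    pairs = {}
    if both.any():
        width = int(lo.max()) + 1
        code = up[both] * width + lo[both]
        vals, counts = np.unique(code, return_counts=True)
        for v, c in zip(vals, counts):
            pairs[(int(v // width), int(v % width))] = int(c)
    return pairs, area_u, area_l


def match_adjacent(upper: LabelMask2D, lower: LabelMask2D,
                   iou_threshold: float = 0.8) -> dict[int, int]:
    """One-to-one best-IoU matching between the labels of two adjacent slices.

    Candidate pairs (every pair with non-empty intersection) are accepted
    greedily in descending IoU order, skipping pairs whose member is already
    matched; only pairs with IoU >= ``iou_threshold`` are accepted.  IoU ties
    break by larger intersection, then by smaller (upper, lower) label pair.
    """
    if upper.shape != lower.shape:
        raise ValueError("label masks must share dimensions")
    pairs, area_u, area_l = _label_contingency(upper.labels, lower.labels)
    cand = []
    for (u, l), n_int in pairs.items():
        union = area_u[u] + area_l[l] - n_int
        iou = n_int / union
        if iou >= iou_threshold:
            cand.append((-iou, -n_int, u, l))
    cand.sort()
    mapping: dict[int, int] = {}
    used_lower: set[int] = set()
    for _, _, u, l in cand:
        if u in mapping or l in used_lower:
            continue
        mapping[u] = l
        used_lower.add(l)
    return mapping


def propagate_labels(per_slice: list[LabelMask2D], iou_threshold: float = 0.8,
                     bridge: int = 0):
    """Sequential top-down label propagation.

    Returns ``(volume, log)`` where ``volume`` is a :class:`PetalLabelVolume`
    with one global id namespace and ``log`` records, per slice, each local
    label's global id and the IoU of the match that assigned it (None for
    fresh ids).  With ``bridge > 0``, a label unmatched on the immediately
    preceding slice may match a global id last seen up to ``bridge`` slices
    earlier (off by default; the strict adjacent-frame rule then no longer
    guarantees contiguous supports).
    """
    if not per_slice:
        raise ValueError("need at least one slice")
    shape = per_slice[0].shape
    out_masks: list[np.ndarray] = []
    log: list[dict] = []
    next_global = 1
    # global ids present on the previous relabeled slice
    first = np.zeros(shape, dtype=np.int32)
    local_ids = np.unique(per_slice[0].labels)
    local_ids = local_ids[local_ids > 0]
    for lid in local_ids:
        first[per_slice[0].labels == lid] = next_global
        log.append({"slice": 0, "local_label": int(lid),
                    "global_id": next_global, "iou": None})
        next_global += 1
    out_masks.append(first)
    history: list[np.ndarray] = [first]
    for k in range(1, len(per_slice)):
        cur = per_slice[k]
        if cur.shape != shape:
            raise ValueError("all slices must share dimensions")
        prev_global = LabelMask2D(out_masks[-1], k - 1)
        # mapping: local label on cur -> global id on prev
        fwd = match_adjacent(cur, prev_global, iou_threshold)
        ious = _match_ious(cur.labels, out_masks[-1], fwd)
        if bridge > 0:
            assigned_globals = set(fwd.values())
            for back in range(2, bridge + 2):
                if k - back < 0:
                    break
                older = LabelMask2D(out_masks[k - back], k - back)
                extra = match_adjacent(cur, older, iou_threshold)
                for lid, gid in extra.items():
                    if lid not in fwd and gid not in assigned_globals:
                        fwd[lid] = gid
                        assigned_globals.add(gid)
                        ious[lid] = _match_ious(cur.labels, out_masks[k - back],
                                                {lid: gid})[lid]
        relab = np.zeros(shape, dtype=np.int32)
        local_ids = np.unique(cur.labels)
        local_ids = local_ids[local_ids > 0]
        for lid in local_ids:
            if lid in fwd:
                gid = fwd[lid]
                iou = ious.get(int(lid))
            else:
                gid = next_global
                next_global += 1
                iou = None
            relab[cur.labels == lid] = gid
            log.append({"slice": k, "local_label": int(lid),
                        "global_id": int(gid), "iou": iou})
        out_masks.append(relab)
    vol = PetalLabelVolume([LabelMask2D(m, k) for k, m in enumerate(out_masks)])
    return vol, log


def _match_ious(cur: np.ndarray, prev: np.ndarray, mapping: dict[int, int]) -> dict[int, float]:
    out = {}
    for lid, gid in mapping.items():
        a = cur == lid
        b = prev == gid
        inter = np.logical_and(a, b).sum()
        union = np.logical_or(a, b).sum()
        out[int(lid)] = float(inter / union) if union else 0.0
    return out


def support_intervals(vol: PetalLabelVolume) -> dict[int, tuple[int, int]]:
    """First and last slice index on which each global id appears."""
    out: dict[int, tuple[int, int]] = {}
    for m in vol.masks:
        for gid in m.ids():
            gid = int(gid)
            if gid in out:
                out[gid] = (out[gid][0], m.index)
            else:
                out[gid] = (m.index, m.index)
    return out


def supports_contiguous(vol: PetalLabelVolume) -> bool:
    """True iff every global id's slice support is a contiguous interval."""
    seen: dict[int, list[int]] = {}
    for m in vol.masks:
        for gid in m.ids():
            seen.setdefault(int(gid), []).append(m.index)
    return all(idx == list(range(idx[0], idx[-1] + 1)) for idx in seen.values())
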