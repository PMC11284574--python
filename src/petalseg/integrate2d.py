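"""Per-slice integration of the 360 crop segmentations.

Adjacent crops (1 degree apart) overlap almost entirely, so a correctly
segmented petal appears in both with essentially the same mask.  Two rules
turn the per-angle candidate masks into one label map per slice:

* **Error removal** — if, inside the shared footprint of two adjacent crops,
  one crop's mask overlaps two or more masks of the other crop, the finer
  division is trusted and the single coarse mask is removed.  Both directions
  of every adjacent pair are evaluated against the original (pre-removal)
  sets and all marked masks are deleted at once, so the outcome does not
  depend on processing order.
* **IoU merging** — surviving masks of adjacent crops whose IoU (computed
  within the shared footprint, see below) is >= 0.8 are declared the same
  petal.  Petal groups are the connected components of this match graph
  (union-find), so the result is independent of pair processing order.

IoU is computed with both masks restricted to the shared footprint of the
two strips by default: adjacent strips cover different slice regions near
their ends, so full-mask IoU of a correctly matched petal can be far below
the threshold there.  ``footprint_restricted=False`` switches to full-mask
IoU for comparison.

The angle set is treated as cyclic: the pair (last angle, first angle) is
processed like any other adjacent pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .backends import InstanceSet, SegmentInstance

__all__ = [
    "PetalGroup",
    "project_to_slice",
    "remove_errors",
    "merge_by_iou",
    "rasterize_consensus",
]


@dataclass
class PetalGroup:
    """Masks of one petal collected across crop angles."""

    group_id: int
    member_refs: list[tuple[float, int]]  # (theta_deg, instance_id)
    members: list[SegmentInstance]
    shape: tuple[int, int]

    @property
    def score(self) -> float:
        return float(np.mean([m.score for m in self.members]))

    @property
    def consensus_mask(self) -> np.ndarray:
        """Union of member masks in the slice frame."""
        out = np.zeros(self.shape, dtype=bool)
        flat = out.reshape(-1)
        for m in self.members:
            flat[m.pixels] = True
        return out


def project_to_slice(sets: Mapping[float, InstanceSet],
                     geometries: Mapping[float, tuple[np.ndarray, np.ndarray, np.ndarray]],
                     slice_shape: tuple[int, int]) -> dict[float, InstanceSet]:
    """Back-project per-crop instance sets into the slice frame.

    ``geometries`` maps each angle to its band geometry ``(flat_idx, u, v)``
    (see :func:`petalseg.cropping._band_geometry`).  Instances whose mask does
    not intersect the slice raster are dropped.
    """
    out: dict[float, InstanceSet] = {}
    for theta, iset in sets.items():
        flat_idx, u, v = geometries[theta]
        projected: list[SegmentInstance] = []
        if iset.disjoint and iset.instances:
            lab = np.zeros(iset.shape, dtype=np.int32)
            labflat = lab.reshape(-1)
            for inst in iset.instances:
                labflat[inst.pixels] = inst.instance_id
            band_vals = lab[u, v]
            order = np.argsort(band_vals, kind="stable")
            vals_sorted = band_vals[order]
            for inst in iset.instances:
                lo = np.searchsorted(vals_sorted, inst.instance_id)
                hi = np.searchsorted(vals_sorted, inst.instance_id, side="right")
                if hi > lo:
                    pix = np.sort(flat_idx[order[lo:hi]])
                    projected.append(SegmentInstance(pix, slice_shape, inst.score,
                                                     inst.instance_id, theta))
        else:
            for inst in iset.instances:
                sel = np.zeros(iset.shape, dtype=bool)
                sel.reshape(-1)[inst.pixels] = True
                pix = flat_idx[sel[u, v]]
                if pix.size:
                    projected.append(SegmentInstance(pix, slice_shape, inst.score,
                                                     inst.instance_id, theta))
        out[theta] = InstanceSet(projected, None, iset.slice_index, slice_shape,
                                 disjoint=iset.disjoint)
    return out


def _adjacent_pairs(angles: list[float]) -> list[tuple[float, float]]:
    """Cyclically adjacent angle pairs, each unordered pair once."""
    n = len(angles)
    if n < 2:
        return []
    if n == 2:
        return [(angles[0], angles[1])]
    return [(angles[i], angles[(i + 1) % n]) for i in range(n)]


def _pair_contingency(set_a: InstanceSet, set_b: InstanceSet, shared: np.ndarray):
    """Intersection table of two slice-frame instance sets on shared pixels.

    Returns ``(inter, area_a, area_b)`` where ``inter[i, j]`` is the pixel
    count of instance i of A ∩ instance j of B ∩ shared footprint and
    ``area_*`` are the per-instance areas restricted to the shared footprint.
    Handles overlapping masks within a set by falling back to per-instance
    membership.
    """
    na, nb = len(set_a.instances), len(set_b.instances)
    inter = np.zeros((na, nb), dtype=np.int64)
    area_a = np.zeros(na, dtype=np.int64)
    area_b = np.zeros(nb, dtype=np.int64)
    if na == 0 or nb == 0 or shared.size == 0:
        return inter, area_a, area_b

    def restrict(inst: SegmentInstance) -> np.ndarray:
        pos = np.searchsorted(shared, inst.pixels)
        ok = pos < shared.size
        pos = pos[ok]
        hit = shared[pos] == inst.pixels[ok]
        return pos[hit]

    mem_a = [restrict(i) for i in set_a.instances]
    mem_b = [restrict(i) for i in set_b.instances]
    area_a[:] = [m.size for m in mem_a]
    area_b[:] = [m.size for m in mem_b]
    # code arrays over the shared footprint; valid when masks are disjoint
    if set_a.disjoint and set_b.disjoint:
        code_a = np.zeros(shared.size, dtype=np.int64)
        code_b = np.zeros(shared.size, dtype=np.int64)
        for i, m in enumerate(mem_a, start=1):
            code_a[m] = i
        for j, m in enumerate(mem_b, start=1):
            code_b[m] = j
        both = (code_a > 0) & (code_b > 0)
        if both.any():
            pair = code_a[both] * (nb + 1) + code_b[both]
            counts = np.bincount(pair, minlength=(na + 1) * (nb + 1))
            inter[:, :] = counts.reshape(na + 1, nb + 1)[1:, 1:]
    else:
        flags_b = np.zeros((nb, shared.size), dtype=bool)
        for j, m in enumerate(mem_b):
            flags_b[j, m] = True
        for i, m in enumerate(mem_a):
            if m.size:
                inter[i, :] = flags_b[:, m].sum(axis=1)
    return inter, area_a, area_b


def _shared_footprint(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    return np.intersect1d(fa, fb, assume_unique=True)


def remove_errors(sets: Mapping[float, InstanceSet],
                  footprints: Mapping[float, np.ndarray],
                  min_overlap_px: int = 5):
    """Delete masks that an adjacent crop divides into two or more regions.

    ``sets`` are slice-frame instance sets per angle; ``footprints`` the
    sorted flat-index footprint of each angle's strip.  A mask is marked when,
    restricted to the shared footprint of an adjacent pair, it intersects two
    or more masks of the other crop with at least ``min_overlap_px`` pixels
    each.  Marking is evaluated in both directions of every adjacent pair
    against the original sets; marked masks are then deleted in one pass.

    Returns ``(filtered_sets, removal_log)``; the log lists dicts with the
    angle, instance id and conflicting partner ids of every removed mask.
    """
    angles = sorted(sets)
    marked: set[tuple[float, int]] = set()
    log: list[dict] = []
    for ta, tb in _adjacent_pairs(angles):
        shared = _shared_footprint(footprints[ta], footprints[tb])
        inter, _, _ = _pair_contingency(sets[ta], sets[tb], shared)
        hits = inter >= min_overlap_px
        for i, inst in enumerate(sets[ta].instances):
            partners = np.flatnonzero(hits[i, :])
            if partners.size >= 2:
                ref = (ta, inst.instance_id)
                if ref not in marked:
                    marked.add(ref)
                    log.append({"theta_deg": ta, "instance_id": inst.instance_id,
                                "against_theta_deg": tb,
                                "partners": [sets[tb].instances[j].instance_id
                                             for j in partners]})
        for j, inst in enumerate(sets[tb].instances):
            partners = np.flatnonzero(hits[:, j])
            if partners.size >= 2:
                ref = (tb, inst.instance_id)
                if ref not in marked:
                    marked.add(ref)
                    log.append({"theta_deg": tb, "instance_id": inst.instance_id,
                                "against_theta_deg": ta,
                                "partners": [sets[ta].instances[i].instance_id
                                             for i in partners]})
    filtered = {
        t: InstanceSet([i for i in s.instances if (t, i.instance_id) not in marked],
                       s.frame, s.slice_index, s.shape, disjoint=s.disjoint)
        for t, s in sets.items()
    }
    return filtered, log


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def merge_by_iou(sets: Mapping[float, InstanceSet],
                 footprints: Mapping[float, np.ndarray],
                 iou_threshold: float = 0.8,
                 min_overlap_px: int = 5,
                 footprint_restricted: bool = True) -> list[PetalGroup]:
    """Group masks across angles by adjacent-pair IoU >= threshold.

    Every surviving mask belongs to exactly one group; masks that match
    nothing form singleton groups.  Group ids are assigned in ascending order
    of each group's smallest (theta, instance_id) member, so the output is
    deterministic and independent of pair processing order.
    """
    angles = sorted(sets)
    uf = _UnionFind()
    for t, s in sets.items():
        for inst in s.instances:
            uf.find((t, inst.instance_id))
    for ta, tb in _adjacent_pairs(angles):
        shared = _shared_footprint(footprints[ta], footprints[tb])
        inter, area_a, area_b = _pair_contingency(sets[ta], sets[tb], shared)
        ii, jj = np.nonzero(inter >= max(1, min_overlap_px))
        for i, j in zip(ii, jj):
            a = sets[ta].instances[i]
            b = sets[tb].instances[j]
            if footprint_restricted:
                n_int = inter[i, j]
                union = area_a[i] + area_b[j] - n_int
            else:
                n_int = np.intersect1d(a.pixels, b.pixels, assume_unique=True).size
                union = a.area + b.area - n_int
            if union > 0 and n_int / union >= iou_threshold:
                uf.union((ta, a.instance_id), (tb, b.instance_id))
    groups: dict = {}
    for t in angles:
        for inst in sets[t].instances:
            groups.setdefault(uf.find((t, inst.instance_id)), []).append((t, inst))
    shape = next(iter(sets.values())).shape if sets else (0, 0)
    ordered = sorted(groups.values(), key=lambda ms: min((t, i.instance_id) for t, i in ms))
    out = []
    for gid, members in enumerate(ordered, start=1):
        members = sorted(members, key=lambda m: (m[0], m[1].instance_id))
        out.append(PetalGroup(gid, [(t, i.instance_id) for t, i in members],
                              [i for _, i in members], shape))
    return out


def rasterize_consensus(groups: list[PetalGroup], slice_shape: tuple[int, int],
                        min_region_px: int = 0) -> "LabelMask2D":
    """Fuse groups into one per-slice label map by per-pixel member vote.

    Each pixel is assigned the group with the most member masks covering it
    (ties go to the lowest group id); pixels covered by no member are 0.
    Labels whose final pixel count falls below ``min_region_px`` are cleared
    (0 disables the floor).
    """
    from .io import LabelMask2D

    n = slice_shape[0] * slice_shape[1]
    best_count = np.zeros(n, dtype=np.int32)
    best_group = np.zeros(n, dtype=np.int32)
    counts = np.zeros(n, dtype=np.int32)
    for g in sorted(groups, key=lambda g: g.group_id):
        counts[:] = 0
        for m in g.members:
            counts[m.pixels] += 1
        win = counts > best_count
        best_group[win] = g.group_id
        best_count[win] = counts[win]
    labels = best_group.reshape(slice_shape)
    return LabelMask2D(_apply_region_floor(labels, min_region_px))


def _apply_region_floor(labels: np.ndarray, min_region_px: int) -> np.ndarray:
    if min_region_px > 0:
        ids, sizes = np.unique(labels[labels > 0], return_counts=True)
        small = ids[sizes < min_region_px]
        if small.size:
            labels[np.isin(labels, small)] = 0
    return labels.astype(np.int32)


def rasterize_consensus_majority(groups: list[PetalGroup], slice_shape: tuple[int, int],
                                 center: tuple[float, float], strip_width: int,
                                 min_region_px: int = 0) -> "LabelMask2D":
    """Fuse groups into a label map by majority vote among visible members.

    Each member mask is a noisy nearest-neighbour copy of the same petal, but
    a pixel is only *observable* by the members whose strip band actually
    covers it.  A pixel therefore joins a group's consensus when at least
    half of the member strips that cover it also mark it (cov >= f/2); among
    qualifying groups the one with the most covering members wins, ties going
    to the lowest group id.  Compared with the plain covering-count rule this
    recovers the median petal boundary instead of the union of all jittered
    copies, which matters because the slice->crop->slice nearest-neighbour
    round trip displaces boundaries by up to ~1 px per angle.

    A member strip at angle theta covers a pixel at polar coordinates
    (r, alpha) relative to ``center`` iff |r sin(theta - alpha)| <= width/2;
    the per-pixel count of observing members is evaluated in closed form from
    the sorted member angles.
    """
    from .io import LabelMask2D

    n = slice_shape[0] * slice_shape[1]
    best_count = np.zeros(n, dtype=np.int32)
    best_group = np.zeros(n, dtype=np.int32)
    counts = np.zeros(n, dtype=np.int32)
    rows = np.arange(slice_shape[0], dtype=np.float64)[:, None] - center[0]
    cols = np.arange(slice_shape[1], dtype=np.float64)[None, :] - center[1]
    r_all = np.hypot(rows, cols).reshape(-1)
    a_all = np.degrees(np.arctan2(rows, cols)).reshape(-1) % 360.0
    half_w = strip_width / 2.0
    for g in sorted(groups, key=lambda g: g.group_id):
        counts[:] = 0
        thetas = []
        for m in g.members:
            counts[m.pixels] += 1
            thetas.append(m.source_theta_deg if m.source_theta_deg is not None else 0.0)
        T = np.sort(np.asarray(thetas, dtype=np.float64))
        cand = np.flatnonzero(counts)
        if cand.size == 0:
            continue
        cov = counts[cand]
        r = r_all[cand]
        alpha = a_all[cand]
        with np.errstate(invalid="ignore"):
            w = np.degrees(np.arcsin(np.minimum(1.0, half_w / np.maximum(r, 1e-9))))
        f = np.where(w >= 90.0, float(T.size),
                     _window_count(T, alpha - w, alpha + w)
                     + _window_count(T, alpha + 180.0 - w, alpha + 180.0 + w))
        f = np.maximum(f, cov)  # rounding margins: a member may mark a pixel
        #                         just outside its analytic band
        qual = 2 * cov >= f
        win = np.zeros(n, dtype=bool)
        win[cand[qual]] = True
        win &= counts > best_count
        best_group[win] = g.group_id
        best_count[win] = counts[win]
    labels = best_group.reshape(slice_shape)
    return LabelMask2D(_apply_region_floor(labels, min_region_px))


def _window_count(T: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Count sorted angles T (deg, in [0,360)) inside [lo, hi] mod 360."""
    lo = np.mod(lo, 360.0)
    hi = np.mod(hi, 360.0)
    a = np.searchsorted(T, lo)
    b = np.searchsorted(T, hi, side="right")
    return np.where(lo <= hi, b - a, T.size - a + b)
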