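"""Per-crop instance segmentation: the backend contract and reference backends.

The pipeline is detector-agnostic: anything that maps a :class:`CropImage` to
a set of scored petal masks plugs in.  The externally trained cascade
detector used in production enters through the COCO interchange in
:mod:`petalseg.coco`; this module supplies two self-contained backends:

* :class:`OracleBackend` — reads the ground-truth labels and perturbs them
  with controllable error modes (drops, splits perpendicular to the petal's
  elongation axis, boundary jitter).  It is the test double that lets every
  downstream stage be validated, and its split mode exercises the
  error-removal rule of the 2D integration.
* :class:`ClassicalBackend` — GPU-free Otsu threshold + connected components
  baseline.

Masks are stored as sorted flat pixel-index sets (:class:`SegmentInstance`)
rather than dense grids: a slice holds ~360 x 15 candidate masks during
integration and dense storage would not fit comfortably in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .cropping import CropFrame, CropImage, _forward_cached
from .io import LabelMask2D

__all__ = [
    "SegmentInstance",
    "InstanceSet",
    "SegmentationBackend",
    "segment",
    "OracleBackend",
    "ClassicalBackend",
    "oracle_backend",
    "classical_backend",
]


@dataclass
class SegmentInstance:
    """One candidate petal mask with a confidence score.

    ``pixels`` are sorted flat indices into a raster of ``shape``; the raster
    is the crop (length x width) or the slice, depending on the owning set's
    frame.
    """

    pixels: np.ndarray
    shape: tuple[int, int]
    score: float
    instance_id: int
    source_theta_deg: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.pixels.size == 0:
            raise ValueError("instance mask must be non-empty")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")

    @classmethod
    def from_mask(cls, mask: np.ndarray, score: float, instance_id: int,
                  source_theta_deg: float | None = None) -> "SegmentInstance":
        mask = np.asarray(mask, dtype=bool)
        return cls(np.flatnonzero(mask.reshape(-1)), mask.shape, score,
                   instance_id, source_theta_deg)

    @property
    def area(self) -> int:
        return int(self.pixels.size)

    @property
    def mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out.reshape(-1)[self.pixels] = True
        return out


@dataclass
class InstanceSet:
    """All candidate instances of one crop (or one slice, if frame is None)."""

    instances: list[SegmentInstance]
    frame: CropFrame | None
    slice_index: int
    shape: tuple[int, int]
    disjoint: bool | None = None  # hint: True if masks are known pairwise disjoint

    def __post_init__(self) -> None:
        ids = [inst.instance_id for inst in self.instances]
        if len(ids) != len(set(ids)):
            raise ValueError("instance_ids must be unique within a set")


class SegmentationBackend(Protocol):
    def segment(self, crop: CropImage) -> InstanceSet: ...


class BackendError(RuntimeError):
    pass


def segment(backend: SegmentationBackend, crop: CropImage) -> InstanceSet:
    """Run a backend on one crop, attaching crop identity to any failure."""
    try:
        return backend.segment(crop)
    except Exception as exc:
        raise BackendError(
            f"backend failed on slice {crop.slice_index}, "
            f"theta={crop.frame.theta_deg:g}"
        ) from exc


def _crop_gt_labels(crop: CropImage, gt: LabelMask2D) -> np.ndarray:
    """Ground-truth labels resampled into crop coordinates (fill -> 0)."""
    src = crop.src_flat
    if src is None:
        src, _ = _forward_cached(crop.frame, gt.shape)
    lab = np.zeros(src.shape, dtype=np.int64)
    inb = src >= 0
    lab[inb] = gt.labels.reshape(-1)[src[inb]]
    return lab


class OracleBackend:
    """Ground-truth-derived backend with seeded, controllable error modes.

    For a crop it extracts the GT labels into crop coordinates and takes
    connected components per label.  Each component is then independently

    * dropped with probability ``p_drop``;
    * split with probability ``p_split`` into two components at a random cut
      perpendicular to its elongation axis (the cut position is uniform over
      the central half of the axis extent so both parts are substantial);
    * eroded/dilated by a random offset in [-jitter, +jitter] pixels.

    With all noise off, outputs are exactly the GT components with score 1.0;
    with any noise on, scores are 1 - U(0, 0.2).  ``split_parity`` (0 or 1)
    restricts splitting to crops whose integer angle has that parity, which
    makes adjacent-angle crops disagree about the division of a petal.
    """

    def __init__(self, gt: Sequence[LabelMask2D] | Mapping[int, LabelMask2D],
                 p_drop: float = 0.0, p_split: float = 0.0,
                 boundary_jitter_px: int = 0, rng_seed: int = 0,
                 split_parity: int | None = None) -> None:
        if isinstance(gt, Mapping):
            self._gt = dict(gt)
        else:
            self._gt = {m.index: m for m in gt}
        self.p_drop = float(p_drop)
        self.p_split = float(p_split)
        self.boundary_jitter_px = int(boundary_jitter_px)
        self.rng_seed = int(rng_seed)
        self.split_parity = split_parity
        self._noisy = (self.p_drop > 0 or self.p_split > 0 or self.boundary_jitter_px > 0)

    def segment(self, crop: CropImage) -> InstanceSet:
        if crop.slice_index not in self._gt:
            raise KeyError(f"oracle has no ground truth for slice {crop.slice_index}")
        gtlab = _crop_gt_labels(crop, self._gt[crop.slice_index])
        comp = cc_label(gtlab, background=0, connectivity=2)
        n = comp.max()
        rng = np.random.default_rng(
            [self.rng_seed, crop.slice_index, int(round(crop.frame.theta_deg * 1000))])
        split_here = (self.split_parity is None
                      or int(round(crop.frame.theta_deg)) % 2 == self.split_parity)
        instances: list[SegmentInstance] = []
        next_id = 1
        for k in range(1, n + 1):
            mask = comp == k
            if self.p_drop > 0 and rng.random() < self.p_drop:
                continue
            parts = [mask]
            if self.p_split > 0 and split_here and rng.random() < self.p_split:
                parts = _split_mask(mask, rng)
            if self.boundary_jitter_px > 0:
                parts = [_jitter_mask(p, rng, self.boundary_jitter_px) for p in parts]
                parts = [p for p in parts if p is not None]
            for p in parts:
                score = 1.0 if not self._noisy else float(1.0 - rng.uniform(0.0, 0.2))
                instances.append(SegmentInstance.from_mask(
                    p, score, next_id, crop.frame.theta_deg))
                next_id += 1
        return InstanceSet(instances, crop.frame, crop.slice_index,
                           (crop.frame.length, crop.frame.width),
                           disjoint=(self.boundary_jitter_px == 0))


def _split_mask(mask: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Cut a component in two perpendicular to its principal (elongation) axis."""
    rr, cc = np.nonzero(mask)
    pts = np.stack([rr, cc]).astype(np.float64)
    pts -= pts.mean(axis=1, keepdims=True)
    cov = pts @ pts.T / max(1, pts.shape[1])
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]  # elongation direction
    t = axis @ pts
    lo, hi = t.min(), t.max()
    if hi - lo <= 1e-9:
        return [mask]
    cut = lo + (hi - lo) * rng.uniform(0.25, 0.75)
    a = np.zeros_like(mask)
    b = np.zeros_like(mask)
    sel = t <= cut
    if sel.all() or not sel.any():
        return [mask]
    a[rr[sel], cc[sel]] = True
    b[rr[~sel], cc[~sel]] = True
    return [a, b]


def _jitter_mask(mask: np.ndarray, rng: np.random.Generator, jitter: int) -> np.ndarray | None:
    off = int(rng.integers(-jitter, jitter + 1))
    if off == 0:
        return mask
    if off > 0:
        return ndimage.binary_dilation(mask, iterations=off)
    out = ndimage.binary_erosion(mask, iterations=-off)
    return out if out.any() else None


class ClassicalBackend:
    """Threshold + connected-components baseline (no learning, no GPU).

    Foreground is the set of non-fill crop pixels above an Otsu (or fixed)
    threshold; connected components smaller than ``min_area_px`` are
    discarded.  The score is the component's mean intensity normalized to the
    crop's intensity range, which makes the whole output invariant to affine
    intensity rescaling in Otsu mode.
    """

    def __init__(self, min_area_px: int = 20, threshold_mode: str = "otsu",
                 fixed_threshold: float | None = None) -> None:
        if threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if threshold_mode == "fixed" and fixed_threshold is None:
            raise ValueError("fixed mode needs fixed_threshold")
        self.min_area_px = int(min_area_px)
        self.threshold_mode = threshold_mode
        self.fixed_threshold = fixed_threshold

    def segment(self, crop: CropImage) -> InstanceSet:
        img = np.asarray(crop.pixels, dtype=np.float64)
        shape = (crop.frame.length, crop.frame.width)
        lo, hi = img.min(), img.max()
        instances: list[SegmentInstance] = []
        if hi > lo:
            if self.threshold_mode == "otsu":
                thr = threshold_otsu(img)
            else:
                thr = float(self.fixed_threshold)  # type: ignore[arg-type]
            fg = (img > thr) & ~crop.fill_mask
            comp = cc_label(fg, background=0, connectivity=2)
            next_id = 1
            for k in range(1, comp.max() + 1):
                mask = comp == k
                if mask.sum() < self.min_area_px:
                    continue
                score = float(np.clip((img[mask].mean() - lo) / (hi - lo), 0.0, 1.0))
                instances.append(SegmentInstance.from_mask(
                    mask, score, next_id, crop.frame.theta_deg))
                next_id += 1
        return InstanceSet(instances, crop.frame, crop.slice_index, shape, disjoint=True)


def oracle_backend(gt, p_drop: float = 0.0, p_split: float = 0.0,
                   boundary_jitter_px: int = 0, rng_seed: int = 0,
                   split_parity: int | None = None) -> OracleBackend:
    """Functional constructor mirroring :class:`OracleBackend`."""
    return OracleBackend(gt, p_drop, p_split, boundary_jitter_px, rng_seed, split_parity)


def classical_backend(min_area_px: int = 20, threshold_mode: str = "otsu",
                      fixed_threshold: float | None = None) -> ClassicalBackend:
    return ClassicalBackend(min_area_px, threshold_mode, fixed_threshold)
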