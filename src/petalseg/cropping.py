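"""Rotated long-rectangle strip cropping.

The divide-and-conquer idea: a long thin rectangle (default 900 x 32 px)
centred on the flower is rotated in small angular steps (default 1 deg) and a
strip image is resampled from the slice at every step.  Inside a strip the
petal cross-sections appear nearly straight, which is what makes per-crop
instance segmentation tractable.  This module owns the crop coordinate frame,
nearest-neighbour extraction with noise fill, and the inverse mapping that
back-projects crop-frame masks into slice coordinates.

Coordinate convention
---------------------
``u`` indexes the long axis, ``v`` the short axis.  A crop pixel ``(u, v)``
maps to slice coordinates

    (row, col) = center + R(theta) . (u - (length-1)/2, v - (width-1)/2)

where ``R`` is the counterclockwise rotation matrix in (col, row) axes with
row increasing downward; ``theta = 0`` therefore yields a horizontal strip
whose long axis runs along image columns.  Nearest-neighbour sampling rounds
half-integers away from zero, so results are platform-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io import SliceImage

__all__ = [
    "CropFrame",
    "CropImage",
    "make_crop_frames",
    "crop_to_slice",
    "slice_to_crop",
    "extract_crop",
    "backproject_mask",
    "crop_footprint",
]


@dataclass(frozen=True)
class CropFrame:
    """Placement of one rotated rectangle on a slice."""

    center: tuple[float, float]  # (row, col)
    theta_deg: float
    length: int = 900
    width: int = 32

    def __post_init__(self) -> None:
        if not (self.length >= self.width >= 1):
            raise ValueError("need length >= width >= 1")
        if not (0.0 <= self.theta_deg < 360.0):
            raise ValueError("theta_deg must lie in [0, 360)")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))


@dataclass
class CropImage:
    """The resampled strip cut from one slice.

    ``fill_mask`` flags pixels whose source coordinate fell outside the slice
    raster and was synthesized from background noise.  ``src_flat`` records,
    for every crop pixel, the flat index of its nearest slice pixel (-1 for
    fill positions); backends may use it to avoid recomputing the geometry.
    """

    pixels: np.ndarray
    frame: CropFrame
    fill_mask: np.ndarray
    slice_index: int
    src_flat: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pixels.shape != self.fill_mask.shape:
            raise ValueError("pixels and fill_mask must have identical dimensions")
        expected = (self.frame.length, self.frame.width)
        if self.pixels.shape != expected:
            raise ValueError(f"crop raster {self.pixels.shape} != frame size {expected}")


def make_crop_frames(center: tuple[float, float], length: int = 900, width: int = 32,
                     angle_step_deg: float = 1.0) -> list[CropFrame]:
    """Frames at theta = 0, step, ..., 360 - step.

    ``angle_step_deg`` must divide 360.  Crops at theta and theta+180 cover
    the same physical strip in flipped orientation and are both emitted.
    """
    if angle_step_deg <= 0:
        raise ValueError("angle_step_deg must be positive")
    n = 360.0 / angle_step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"angle_step_deg={angle_step_deg} does not divide 360")
    n = int(round(n))
    return [CropFrame(center, i * angle_step_deg, length, width) for i in range(n)]


def _trig(theta_deg: float) -> tuple[float, float]:
    t = math.radians(theta_deg)
    return math.cos(t), math.sin(t)


def crop_to_slice(frame: CropFrame, u, v):
    """Map crop coordinates (u, v) to real-valued slice coordinates (row, col)."""
    ct, st = _trig(frame.theta_deg)
    du = np.asarray(u, dtype=np.float64) - (frame.length - 1) / 2.0
    dv = np.asarray(v, dtype=np.float64) - (frame.width - 1) / 2.0
    row = frame.center[0] + du * st + dv * ct
    col = frame.center[1] + du * ct - dv * st
    return row, col


def slice_to_crop(frame: CropFrame, row, col):
    """Exact inverse of :func:`crop_to_slice`."""
    ct, st = _trig(frame.theta_deg)
    dr = np.asarray(row, dtype=np.float64) - frame.center[0]
    dc = np.asarray(col, dtype=np.float64) - frame.center[1]
    du = dc * ct + dr * st
    dv = -dc * st + dr * ct
    return du + (frame.length - 1) / 2.0, dv + (frame.width - 1) / 2.0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (fixed across platforms)."""
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def _forward_geometry(frame: CropFrame, slice_shape: tuple[int, int]):
    """Nearest-neighbour source index for every crop pixel.

    Returns ``(src_flat, inbounds)`` where ``src_flat`` has shape
    (length, width) with flat slice indices (-1 where out of bounds).
    """
    u = np.arange(frame.length, dtype=np.float64)[:, None]
    v = np.arange(frame.width, dtype=np.float64)[None, :]
    row, col = crop_to_slice(frame, u + np.zeros_like(v), v + np.zeros_like(u))
    ri = _round_half_away(row)
    ci = _round_half_away(col)
    inb = (ri >= 0) & (ri < slice_shape[0]) & (ci >= 0) & (ci < slice_shape[1])
    src = np.where(inb, ri * slice_shape[1] + ci, -1)
    return src, inb


def _band_geometry(frame: CropFrame, slice_shape: tuple[int, int]):
    """Inverse nearest-neighbour mapping restricted to the strip footprint.

    Returns ``(flat_idx, u_idx, v_idx)``: the sorted flat indices of slice
    pixels whose nearest crop coordinate is inside the crop raster and whose
    crop pixel is itself sourced from inside the slice (fill positions never
    project), together with the nearest crop coordinates of those pixels.
    """
    rows, cols = slice_shape
    ct, st = _trig(frame.theta_deg)
    r = np.arange(rows, dtype=np.float64)[:, None] - frame.center[0]
    c = np.arange(cols, dtype=np.float64)[None, :] - frame.center[1]
    dv = -c * st + r * ct
    half_w = (frame.width - 1) / 2.0 + 0.5
    band = np.abs(dv) <= half_w  # cheap prefilter on the short axis
    if not band.any():
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    rr, cc = np.nonzero(band)
    du = (cc - frame.center[1]) * ct + (rr - frame.center[0]) * st
    u = _round_half_away(du + (frame.length - 1) / 2.0)
    v = _round_half_away((-(cc - frame.center[1]) * st + (rr - frame.center[0]) * ct)
                         + (frame.width - 1) / 2.0)
    ok = (u >= 0) & (u < frame.length) & (v >= 0) & (v < frame.width)
    rr, cc, u, v = rr[ok], cc[ok], u[ok], v[ok]
    # exclude slice pixels whose nearest crop pixel is a fill position
    src, _ = _forward_geometry(frame, slice_shape)
    keep = src[u, v] >= 0
    flat = rr[keep] * cols + cc[keep]
    return flat, u[keep], v[keep]


# Small memoized fronts for the public per-frame API; the pipeline manages its
# own per-slice geometry explicitly to keep memory bounded.
@lru_cache(maxsize=64)
def _forward_cached(frame: CropFrame, slice_shape: tuple[int, int]):
    return _forward_geometry(frame, slice_shape)


@lru_cache(maxsize=64)
def _band_cached(frame: CropFrame, slice_shape: tuple[int, int]):
    return _band_geometry(frame, slice_shape)


def extract_crop(img: SliceImage, frame: CropFrame, bg_mean: float,
                 fill_variance: float = 5.0, rng_seed: int = 0) -> CropImage:
    """Nearest-neighbour strip extraction with seeded Gaussian noise fill.

    Crop pixels whose source coordinate falls outside the slice raster are
    drawn i.i.d. from Normal(bg_mean, fill_variance) — the fill *variance* is
    5 by default, i.e. std = sqrt(5) — clamped to the image dtype range, and
    flagged in ``fill_mask``.  Deterministic for a fixed seed.
    """
    src, inb = _forward_cached(frame, img.shape)
    pixels = np.empty((frame.length, frame.width), dtype=img.pixels.dtype)
    flat = img.pixels.reshape(-1)
    pixels[inb] = flat[src[inb]]
    n_fill = int((~inb).sum())
    if n_fill:
        rng = np.random.default_rng(rng_seed)
        draws = rng.normal(float(bg_mean), math.sqrt(float(fill_variance)), size=n_fill)
        if np.issubdtype(img.pixels.dtype, np.integer):
            info = np.iinfo(img.pixels.dtype)
            draws = np.clip(np.rint(draws), info.min, info.max)
        pixels[~inb] = draws.astype(img.pixels.dtype)
    return CropImage(pixels=pixels, frame=frame, fill_mask=~inb,
                     slice_index=img.index, src_flat=src)


def backproject_mask(mask: np.ndarray, frame: CropFrame,
                     slice_shape: tuple[int, int]) -> np.ndarray:
    """Project a crop-frame binary mask into slice coordinates.

    Each slice pixel inside the strip footprint takes the mask value at its
    nearest crop coordinate; everything else is 0.  Fill positions never
    project.
    """
    mask = np.asarray(mask)
    if mask.shape != (frame.length, frame.width):
        raise ValueError(f"mask shape {mask.shape} != frame size {(frame.length, frame.width)}")
    flat, u, v = _band_cached(frame, slice_shape)
    out = np.zeros(slice_shape, dtype=bool)
    out.reshape(-1)[flat[mask[u, v].astype(bool)]] = True
    return out


def crop_footprint(frame: CropFrame, slice_shape: tuple[int, int]) -> np.ndarray:
    """Boolean slice-frame footprint of the strip (back-projected all-true mask)."""
    flat, _, _ = _band_cached(frame, slice_shape)
    out = np.zeros(slice_shape, dtype=bool)
    out.reshape(-1)[flat] = True
    return out


def footprint_pixels(frame: CropFrame, slice_shape: tuple[int, int]) -> np.ndarray:
    """Sorted flat slice indices of the strip footprint (set form of the above)."""
    flat, _, _ = _band_cached(frame, slice_shape)
    return flat
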