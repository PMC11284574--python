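"""Reading/writing CT slice stacks and label volumes, plus slice-level statistics.

A flower CT scan arrives as a stack of grayscale cross-sections (multi-page
TIFF or a directory of single-page TIFF/PNG files).  This module defines the
in-memory containers used throughout the package (:class:`SliceImage`,
:class:`Volume`, :class:`LabelMask2D`, :class:`PetalLabelVolume`), the disk
round-trip for them, optional non-local-means denoising, and the two image
statistics the cropping stage needs: the flower center and the mean background
intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_nl_means

__all__ = [
    "SliceImage",
    "Volume",
    "LabelMask2D",
    "PetalLabelVolume",
    "read_volume",
    "write_label_volume",
    "read_label_volume",
    "denoise_nlm",
    "estimate_center",
    "background_stats",
    "label_to_rgb",
    "write_label_pngs",
]


@dataclass
class SliceImage:
    """One grayscale CT cross-section.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensity raster in arbitrary scalar units.
    pixel_size_um : float
        Physical side length of one pixel in micrometres.
    index : int
        0-based position in the stack; 0 is the top of the flower.
    """

    pixels: np.ndarray
    pixel_size_um: float
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("SliceImage.pixels must be a non-empty 2D array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class Volume:
    """Ordered stack of slices (top to bottom) with uniform geometry."""

    slices: list[SliceImage]
    slice_thickness_um: float

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("Volume needs at least one slice")
        if not self.slice_thickness_um > 0:
            raise ValueError("slice_thickness_um must be positive")
        shape = self.slices[0].shape
        psz = self.slices[0].pixel_size_um
        for k, s in enumerate(self.slices):
            if s.shape != shape:
                raise ValueError(f"slice {k} has shape {s.shape}, expected {shape}")
            if s.pixel_size_um != psz:
                raise ValueError("all slices must share pixel_size_um")
            s.index = k

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class LabelMask2D:
    """Integer petal labels for one slice; 0 is background."""

    labels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class PetalLabelVolume:
    """Per-slice label masks sharing one global label namespace.

    A given label id denotes the same petal on every slice where it appears.
    """

    masks: list[LabelMask2D]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("PetalLabelVolume needs at least one mask")
        shape = self.masks[0].shape
        for k, m in enumerate(self.masks):
            if m.shape != shape:
                raise ValueError(f"mask {k} has shape {m.shape}, expected {shape}")
            m.index = k

    def to_array(self) -> np.ndarray:
        return np.stack([m.labels for m in self.masks])

    def ids(self) -> np.ndarray:
        u = np.unique(self.to_array())
        return u[u > 0]

    def __len__(self) -> int:
        return len(self.masks)


_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


def _to_gray(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.ndim == 3:
        # RGB(A) input: unweighted channel mean over the color channels.
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{name}: cannot interpret array of shape {arr.shape} as a slice")
    return arr


def read_volume(path: str | Path, pixel_size_um: float, slice_thickness_um: float) -> Volume:
    """Read a slice stack from a multi-page TIFF or a directory of images.

    Directory entries are ordered lexicographically by filename; multi-page
    TIFFs by page order.  RGB inputs are converted to grayscale by channel
    mean.  Raises if slices disagree in raster size, naming the offending
    file.
    """
    path = Path(path)
    arrays: list[np.ndarray] = []
    names: list[str] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise ValueError(f"no TIFF/PNG slices found in {path}")
        for f in files:
            try:
                arr = iio.imread(f)
            except Exception as exc:  # pragma: no cover - backend specific
                raise ValueError(f"unreadable slice file {f}") from exc
            arrays.append(_to_gray(np.asarray(arr), str(f)))
            names.append(str(f))
    else:
        try:
            pages = tifffile.imread(path)
        except Exception as exc:
            raise ValueError(f"unreadable stack {path}") from exc
        pages = np.asarray(pages)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim == 4:  # pages x rows x cols x channels
            pages = pages[..., :3].mean(axis=-1)
        arrays = list(pages)
        names = [f"{path}[page {k}]" for k in range(len(arrays))]
    shape = arrays[0].shape
    for name, arr in zip(names, arrays):
        if arr.shape != shape:
            raise ValueError(f"slice {name} has shape {arr.shape}, expected {shape}")
    slices = [SliceImage(a, pixel_size_um, k) for k, a in enumerate(arrays)]
    return Volume(slices, slice_thickness_um)


def write_label_volume(vol: PetalLabelVolume, path: str | Path) -> None:
    """Write a label volume as a lossless multi-page unsigned TIFF.

    16-bit pages are used unless any label exceeds 65535, in which case the
    file is widened to 32 bit; labels are never truncated.
    """
    arr = vol.to_array()
    dtype = np.uint16 if arr.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(Path(path), arr.astype(dtype), photometric="minisblack")


def read_label_volume(path: str | Path) -> PetalLabelVolume:
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim == 2:
        arr = arr[None]
    return PetalLabelVolume([LabelMask2D(a.astype(np.int64), k) for k, a in enumerate(arr)])


def denoise_nlm(img: SliceImage, h: float = 6.0) -> SliceImage:
    """Non-local-means denoising with filter strength ``h`` (in intensity units).

    ``h = 0`` is an exact no-op.  Raster dimensions are unchanged.
    """
    if h < 0:
        raise ValueError("h must be non-negative")
    if h == 0:
        return SliceImage(img.pixels.copy(), img.pixel_size_um, img.index)
    out = denoise_nl_means(img.pixels.astype(np.float64), h=float(h), fast_mode=True,
                           patch_size=5, patch_distance=6, preserve_range=True)
    if np.issubdtype(img.pixels.dtype, np.integer):
        info = np.iinfo(img.pixels.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(img.pixels.dtype)
    else:
        out = out.astype(img.pixels.dtype)
    return SliceImage(out, img.pixel_size_um, img.index)


def _otsu_foreground(pixels: np.ndarray) -> np.ndarray | None:
    """Boolean foreground mask by Otsu thresholding, or None if degenerate."""
    if np.ptp(pixels) == 0:
        return None
    try:
        thr = threshold_otsu(np.asarray(pixels, dtype=np.float64))
    except ValueError:
        return None
    fg = pixels > thr
    if not fg.any():
        return None
    return fg


def estimate_center(img: SliceImage, override: tuple[float, float] | None = None) -> tuple[float, float]:
    """Locate the flower center as the intensity centroid of the Otsu foreground.

    A user-supplied ``override`` is returned verbatim.  If the foreground is
    empty the geometric image center is returned with a warning.
    """
    if override is not None:
        return (float(override[0]), float(override[1]))
    fg = _otsu_foreground(img.pixels)
    if fg is None:
        warnings.warn("empty foreground; falling back to geometric image center", stacklevel=2)
        r, c = img.shape
        return ((r - 1) / 2.0, (c - 1) / 2.0)
    w = np.asarray(img.pixels, dtype=np.float64)[fg]
    rr, cc = np.nonzero(fg)
    total = w.sum()
    return (float((rr * w).sum() / total), float((cc * w).sum() / total))


def background_stats(img: SliceImage) -> float:
    """Mean intensity of the sub-Otsu-threshold ("background") pixels."""
    pixels = np.asarray(img.pixels, dtype=np.float64)
    if np.ptp(pixels) == 0:
        return float(pixels.flat[0])
    thr = threshold_otsu(pixels)
    bg = pixels[pixels <= thr]
    if bg.size == 0:  # pragma: no cover - Otsu always leaves a low class
        return float(pixels.min())
    return float(bg.mean())


_GOLDEN_ANGLE_DEG = 137.50776405003785


def label_to_rgb(labels: np.ndarray) -> np.ndarray:
    """Deterministic label -> color map (golden-angle hue stepping), uint8 RGB."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        hue = (lab * _GOLDEN_ANGLE_DEG / 360.0) % 1.0
        out[labels == lab] = _hsv_to_rgb255(hue, 0.85, 1.0)
    return out


def _hsv_to_rgb255(h: float, s: float, v: float) -> tuple[int, int, int]:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    r, g, b = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return (int(r * 255), int(g * 255), int(b * 255))


def write_label_pngs(vol: PetalLabelVolume, out_dir: str | Path) -> list[Path]:
    """Render each slice of a label volume as a color PNG."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in vol.masks:
        p = out_dir / f"labels{m.index:04d}.png"
        iio.imwrite(p, label_to_rgb(m.labels))
        paths.append(p)
    return paths
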