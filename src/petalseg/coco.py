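"""COCO-JSON interchange for per-crop instance segmentations.

An externally trained detector (e.g. a cascade instance-segmentation network
run in its own environment) replaces the built-in backends through two
standard files:

* an *annotation* file (written by :func:`export_coco` together with the crop
  PNGs) that the external tool trains/predicts on, and
* a *result* file (read by :func:`import_coco`) holding scored detections
  whose ``segmentation`` is an RLE (uncompressed counts list or compressed
  counts string) or a polygon.

A sidecar JSON written alongside the annotation file binds every COCO image
id to its :class:`~petalseg.cropping.CropFrame`, so imported detections can
be back-projected onto the slices.  The RLE codec (column-major runs,
compressed LEB128-style string with difference coding) is implemented here
and round-trips masks losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import imageio.v3 as iio
from skimage.draw import polygon as draw_polygon

from .backends import InstanceSet, SegmentInstance, OracleBackend
from .cropping import CropFrame, CropImage
from .io import LabelMask2D

__all__ = [
    "mask_to_rle",
    "rle_to_mask",
    "rle_encode_counts",
    "rle_decode_counts",
    "polygon_to_mask",
    "export_coco",
    "import_coco",
]


# ---------------------------------------------------------------- RLE codec

def mask_to_rle(mask: np.ndarray, compress: bool = False) -> dict:
    """Encode a binary mask as a COCO RLE dict (column-major run lengths)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.T.reshape(-1)  # Fortran order
    # runs of equal values, starting with the count of zeros
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        counts = [0] + counts
    if not flat.size:
        counts = [0]
    rle = {"size": [int(h), int(w)], "counts": counts}
    if compress:
        rle["counts"] = rle_encode_counts(counts)
    return rle


def rle_to_mask(rle: Mapping) -> np.ndarray:
    """Decode a COCO RLE dict (list or compressed-string counts) to a mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    if isinstance(counts, (str, bytes)):
        counts = rle_decode_counts(counts)
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape(w, h).T


def rle_encode_counts(counts: Iterable[int]) -> str:
    """Compress run counts to the COCO string form (difference-coded LEB128)."""
    counts = list(counts)
    out = []
    for i, x in enumerate(counts):
        if i > 2:
            x -= counts[i - 2]
        more = True
        while more:
            c = x & 0x1F
            x >>= 5
            more = (x != -1) if (c & 0x10) else (x != 0)
            if more:
                c |= 0x20
            out.append(chr(c + 48))
    return "".join(out)


def rle_decode_counts(s: str | bytes) -> list[int]:
    """Inverse of :func:`rle_encode_counts`."""
    if isinstance(s, bytes):
        s = s.decode("ascii")
    counts: list[int] = []
    i = 0
    while i < len(s):
        x = 0
        k = 0
        while True:
            c = ord(s[i]) - 48
            x |= (c & 0x1F) << (5 * k)
            i += 1
            k += 1
            if not (c & 0x20):
                if c & 0x10:
                    x |= -1 << (5 * k)
                break
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return counts


def polygon_to_mask(poly: list[float], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a COCO polygon ([x0, y0, x1, y1, ...]) onto a raster."""
    xy = np.asarray(poly, dtype=np.float64).reshape(-1, 2)
    rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


# ------------------------------------------------------------- export/import

def _image_record(idx: int, crop: CropImage) -> dict:
    theta = crop.frame.theta_deg
    if float(theta).is_integer():
        name = f"slice{crop.slice_index:04d}_ang{int(theta):03d}.png"
    else:
        name = f"slice{crop.slice_index:04d}_ang{theta:07.3f}.png"
    return {
        "id": idx,
        "file_name": name,
        "height": crop.frame.length,
        "width": crop.frame.width,
        "slice_index": crop.slice_index,
        "frame": {
            "center": [crop.frame.center[0], crop.frame.center[1]],
            "theta_deg": crop.frame.theta_deg,
            "length": crop.frame.length,
            "width": crop.frame.width,
        },
    }


def write_sidecar(crops: list[CropImage], path: str | Path) -> None:
    """Record the CropFrame of every exported crop image id."""
    records = [_image_record(i + 1, c) for i, c in enumerate(crops)]
    Path(path).write_text(json.dumps({"images": records}, indent=1))


def export_coco(crops: list[CropImage], gt: list[LabelMask2D], path: str | Path,
                write_images: bool = True, compress: bool = True) -> None:
    """Write COCO instance annotations (+ crop PNGs and frame sidecar).

    Ground-truth components are extracted into each crop's coordinates by the
    zero-noise oracle, so an external detector trained on this file and
    evaluated with :func:`import_coco` sees exactly the geometry the built-in
    pipeline uses.  The sidecar JSON lands next to ``path`` with suffix
    ``.frames.json``.
    """
    path = Path(path)
    oracle = OracleBackend(gt)
    images = []
    annotations = []
    ann_id = 1
    for i, crop in enumerate(crops):
        rec = _image_record(i + 1, crop)
        images.append(rec)
        if write_images:
            img = crop.pixels
            if not np.issubdtype(img.dtype, np.unsignedinteger):
                lo, hi = float(img.min()), float(img.max())
                scale = 255.0 / (hi - lo) if hi > lo else 1.0
                img = np.clip((img - lo) * scale, 0, 255).astype(np.uint8)
            iio.imwrite(path.parent / rec["file_name"], img)
        for inst in oracle.segment(crop).instances:
            mask = inst.mask
            rr, cc = np.nonzero(mask)
            annotations.append({
                "id": ann_id,
                "image_id": rec["id"],
                "category_id": 1,
                "segmentation": mask_to_rle(mask, compress=compress),
                "area": int(inst.area),
                "bbox": [int(cc.min()), int(rr.min()),
                         int(cc.max() - cc.min() + 1), int(rr.max() - rr.min() + 1)],
                "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "petal"}],
    }
    path.write_text(json.dumps(doc))
    write_sidecar(crops, path.with_suffix(".frames.json"))


def import_coco(path: str | Path, frames: str | Path | Mapping,
                default_score: float = 1.0) -> dict[tuple[int, float], InstanceSet]:
    """Read COCO detections into per-crop instance sets.

    ``path`` may be a COCO *result* file (a list of detection dicts) or a full
    annotation file (its ``annotations`` are then imported with
    ``default_score``).  ``frames`` is the sidecar JSON (path or parsed dict)
    binding image ids to crop frames.  Returns a dict keyed by
    ``(slice_index, theta_deg)``.  Unknown image ids raise, listing them.
    """
    doc = json.loads(Path(path).read_text())
    if isinstance(doc, dict) and "annotations" in doc:
        dets = [dict(a, score=a.get("score", default_score)) for a in doc["annotations"]]
    else:
        dets = list(doc)
    if not isinstance(frames, Mapping):
        frames = json.loads(Path(frames).read_text())
    frame_by_id: dict[int, dict] = {rec["id"]: rec for rec in frames["images"]}
    unknown = sorted({d["image_id"] for d in dets} - set(frame_by_id))
    if unknown:
        raise ValueError(f"detections reference unknown image ids: {unknown}")
    grouped: dict[int, list[dict]] = {}
    for d in dets:
        grouped.setdefault(d["image_id"], []).append(d)
    out: dict[tuple[int, float], InstanceSet] = {}
    for img_id, rec in frame_by_id.items():
        f = rec["frame"]
        frame = CropFrame((f["center"][0], f["center"][1]), f["theta_deg"],
                          f["length"], f["width"])
        shape = (frame.length, frame.width)
        instances = []
        for k, d in enumerate(grouped.get(img_id, []), start=1):
            seg = d["segmentation"]
            if isinstance(seg, dict):
                mask = rle_to_mask(seg)
            else:
                polys = seg if isinstance(seg[0], (list, tuple)) else [seg]
                mask = np.zeros(shape, dtype=bool)
                for p in polys:
                    mask |= polygon_to_mask(p, shape)
            if mask.shape != shape:
                raise ValueError(
                    f"mask shape {mask.shape} != crop size {shape} for image {img_id}")
            if not mask.any():
                continue
            instances.append(SegmentInstance.from_mask(
                mask, float(d.get("score", default_score)), k, frame.theta_deg))
        key = (rec["slice_index"], frame.theta_deg)
        out[key] = InstanceSet(instances, frame, rec["slice_index"], shape)
    return out
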