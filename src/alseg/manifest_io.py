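"""Dataset readers and writers.

A corpus on disk is a directory of grayscale PNG/TIFF images (8- or 16-bit;
DICOM read is optional) plus per-class binary mask PNGs, tied together by a
manifest CSV with columns ``id, image_path, mask_bg_path, mask_femur_path,
mask_acetabulum_path, split``. Paths are relative to the manifest's
directory. Images are rescaled to [0, 1] by their dtype range; masks are
validated strictly binary.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np

from .core_types import ImageSample, MaskStack

MANIFEST_COLUMNS = (
    "id",
    "image_path",
    "mask_bg_path",
    "mask_femur_path",
    "mask_acetabulum_path",
    "split",
)

_MASK_KEYS = ("mask_bg_path", "mask_femur_path", "mask_acetabulum_path")


def _read_gray(path: Path) -> np.ndarray:
    """Read a grayscale image into [0, 1], honoring 8/16-bit ranges."""
    if path.suffix.lower() in {".dcm", ".dicom"}:
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - soft dependency
            raise ValueError(f"{path}: DICOM support requires pydicom") from exc
        try:
            arr = pydicom.dcmread(path).pixel_array.astype(np.float64)
        except Exception as exc:
            raise ValueError(f"{path}: unreadable DICOM ({exc})") from exc
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an accidental RGB to gray
        arr = arr.mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _read_binary_mask(path: Path, channel: str) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 1, 255, 65535}:
        raise ValueError(f"{path}: non-binary {channel} mask (values {values[:5]})")
    return (arr > 0).astype(np.uint8)


def save_corpus(
    samples: Sequence[ImageSample],
    out_dir: str | Path,
    splits: Mapping[str, str] | None = None,
) -> Path:
    """Write images, per-class masks, and the manifest CSV; returns its path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        if s.mask is None:
            raise ValueError(f"sample {s.id!r} has no mask to save")
        img_rel = f"images/{s.id}.png"
        iio.imwrite(out / img_rel, np.round(s.pixels * 255).astype(np.uint8))
        mask_rels = []
        for name, ch in zip(("bg", "femur", "acetabulum"), s.mask.channels):
            rel = f"masks/{s.id}_{name}.png"
            iio.imwrite(out / rel, (ch * 255).astype(np.uint8))
            mask_rels.append(rel)
        rows.append(
            {
                "id": s.id,
                "image_path": img_rel,
                "mask_bg_path": mask_rels[0],
                "mask_femur_path": mask_rels[1],
                "mask_acetabulum_path": mask_rels[2],
                "split": (splits or {}).get(s.id, ""),
            }
        )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def load_manifest(path: str | Path) -> list[ImageSample]:
    """Load a manifest CSV into in-memory samples.

    Rejects duplicated ids, missing files (naming the row), and non-binary
    masks (naming the channel).
    """
    path = Path(path)
    base = path.parent
    samples: list[ImageSample] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(MANIFEST_COLUMNS[:-1]) - set(reader.fieldnames or ())
        if missing_cols:
            raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
        for i, row in enumerate(reader):
            sid = row["id"]
            if sid in seen:
                raise ValueError(f"duplicate sample id in manifest: {sid!r}")
            seen.add(sid)
            img_path = base / row["image_path"]
            if not img_path.exists():
                raise ValueError(f"row {i} (id {sid!r}): missing file {img_path}")
            pixels = _read_gray(img_path)
            channels = []
            for key, channel_name in zip(_MASK_KEYS, ("background", "femur", "acetabulum")):
                mpath = base / row[key]
                if not mpath.exists():
                    raise ValueError(f"row {i} (id {sid!r}): missing file {mpath}")
                channels.append(_read_binary_mask(mpath, channel_name))
            samples.append(
                ImageSample(id=sid, pixels=pixels, mask=MaskStack(np.stack(channels)))
            )
    return samples


def load_split_map(path: str | Path) -> dict[str, str]:
    """The id → split assignment recorded in a manifest."""
    with open(path, newline="") as fh:
        return {row["id"]: row.get("split", "") for row in csv.DictReader(fh)}
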