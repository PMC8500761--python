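"""Raster, table, and model I/O.

Images travel as 8- or 16-bit grayscale PNG/TIFF and are normalized to
floats in [0, 1] on read; masks and edge maps are written as 16-bit PNG
(0 / 65535).  Feature tables are CSV, models and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .svm import KernelSVC

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_model",
    "load_model",
]


def read_image(path) -> np.ndarray:
    """Read a grayscale image and normalize it to floats in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    raw = iio.imread(path)
    if raw.ndim == 3:  # collapse RGB(A) via luminance-free mean
        raw = raw[..., :3].mean(axis=-1)
    a = np.asarray(raw, dtype=float)
    if np.issubdtype(raw.dtype, np.integer):
        a = a / float(np.iinfo(raw.dtype).max)
    return np.clip(a, 0.0, 1.0)


def write_image(path, img) -> None:
    """Write floats in [0, 1] as 16-bit grayscale PNG/TIFF."""
    a = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    out = np.round(a * 65535.0).astype(np.uint16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), out)


def read_mask(path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel counts as 1)."""
    return (read_image(path) > 0.5).astype(np.uint8)


def write_mask(path, mask) -> None:
    write_image(path, np.asarray(mask).astype(bool).astype(float))


def save_model(path, model: KernelSVC, meta: dict | None = None) -> None:
    doc = {"model": model.to_dict(), "meta": meta or {}}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path) -> tuple[KernelSVC, dict]:
    doc = json.loads(Path(path).read_text())
    return KernelSVC.from_dict(doc["model"]), doc.get("meta", {})
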