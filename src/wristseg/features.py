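"""Per-edge-pixel features, ground-truth labelling, and lesion-mask
reconstruction from classified edges.

Each detected edge pixel gets a 7-component descriptor computed from the
image and its gradient field over an odd square window (reflect-padded):

    [local mean, local std, gradient magnitude, cos(direction),
     sin(direction), normalized row, normalized col]

The descriptor is deliberately minimal, local, and orientation-aware.
For phantoms with known truth, an edge pixel is labelled lesion-positive
(+1) iff it lies within Chebyshev distance 1 of the lesion-region
boundary, else -1.  At segmentation time the positively classified edge
pixels are turned into a filled lesion mask by a 3x3 morphological
closing followed by interior hole filling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .edges import GradientField
from .svm import KernelSVC

__all__ = [
    "FEATURE_NAMES",
    "extract_edge_features",
    "label_edge_pixels",
    "mask_boundary",
    "edges_to_mask",
    "classify_edges",
]

FEATURE_NAMES = (
    "local_mean",
    "local_std",
    "grad_mag",
    "cos_dir",
    "sin_dir",
    "row_norm",
    "col_norm",
)

_EIGHT = np.ones((3, 3), dtype=bool)


def extract_edge_features(
    img, edges, field: GradientField, window: int = 5
) -> pd.DataFrame:
    """One feature row per edge pixel.

    Returns a DataFrame with columns ``row``, ``col`` and the seven
    :data:`FEATURE_NAMES`; empty (zero rows) for an empty edge map.
    Local mean and std use the ``window`` x ``window`` neighborhood of
    the reflect-padded image (population std, ddof=0).
    """
    a = np.asarray(img, dtype=float)
    e = np.asarray(edges).astype(bool)
    if a.shape != e.shape:
        raise ValueError("image and edge map shapes differ")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    h, w = a.shape
    rows, cols = np.nonzero(e)
    if rows.size == 0:
        return pd.DataFrame(columns=["row", "col", *FEATURE_NAMES])

    local_mean = ndimage.uniform_filter(a, size=window, mode="reflect")
    local_sq = ndimage.uniform_filter(a * a, size=window, mode="reflect")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    local_std = np.sqrt(local_var)

    theta = field.direction
    denom_r = max(h - 1, 1)
    denom_c = max(w - 1, 1)
    data = {
        "row": rows,
        "col": cols,
        "local_mean": local_mean[rows, cols],
        "local_std": local_std[rows, cols],
        "grad_mag": field.magnitude[rows, cols],
        "cos_dir": np.cos(theta[rows, cols]),
        "sin_dir": np.sin(theta[rows, cols]),
        "row_norm": rows / denom_r,
        "col_norm": cols / denom_c,
    }
    return pd.DataFrame(data)


def mask_boundary(mask) -> np.ndarray:
    """Pixels of a binary mask with at least one 4-neighbor outside it."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return m & ~eroded


def label_edge_pixels(features: pd.DataFrame, lesion_mask) -> np.ndarray:
    """+1 for edge pixels within Chebyshev distance 1 of the lesion
    boundary, -1 otherwise."""
    boundary = mask_boundary(lesion_mask)
    near = ndimage.binary_dilation(boundary, structure=_EIGHT)
    rows = features["row"].to_numpy(dtype=int)
    cols = features["col"].to_numpy(dtype=int)
    return np.where(near[rows, cols], 1, -1)


def edges_to_mask(positive_edges, close_size: int = 3) -> np.ndarray:
    """Closed-and-filled region mask from positively classified edge pixels."""
    pos = np.asarray(positive_edges).astype(bool)
    if not pos.any():
        return np.zeros(pos.shape, dtype=np.uint8)
    closed = ndimage.binary_closing(
        pos, structure=np.ones((close_size, close_size), dtype=bool)
    )
    filled = ndimage.binary_fill_holes(closed)
    return filled.astype(np.uint8)


def classify_edges(
    img,
    edges,
    field: GradientField,
    model: KernelSVC,
    window: int = 5,
    close_size: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify each edge pixel as lesion/non-lesion and rebuild the mask.

    Returns ``(lesion_edges, lesion_mask)`` as uint8 maps.  The
    classification is per-pixel, hence invariant to enumeration order;
    an empty edge map (or an all-negative classification) yields empty
    outputs.
    """
    e = np.asarray(edges).astype(bool)
    feats = extract_edge_features(img, e, field, window=window)
    lesion_edges = np.zeros(e.shape, dtype=np.uint8)
    if len(feats) == 0:
        return lesion_edges, np.zeros(e.shape, dtype=np.uint8)
    pred = model.predict(feats[list(FEATURE_NAMES)].to_numpy())
    pos = pred == model.classes_[1]
    rows = feats["row"].to_numpy(dtype=int)[pos]
    cols = feats["col"].to_numpy(dtype=int)[pos]
    lesion_edges[rows, cols] = 1
    return lesion_edges, edges_to_mask(lesion_edges, close_size=close_size)
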