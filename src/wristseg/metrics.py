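"""Segmentation and image-quality metric suite.

Image fidelity: MSE, PSNR (10*log10(pe_max^2 / MSE), +inf when the
images coincide), windowed SSIM (brightness x contrast x structure over
8x8 sliding windows with the conventional stabilizing constants), and
the Pratt figure of merit for edge maps.

Edge quality: a continuity index CI — the size-weighted mean, over
8-connected edge segments, of each segment's fraction of pixels with at
least two edge neighbors (so closed 1-pixel-wide curves score ~1 and
scattered single pixels score 0; the value is capped just below 1) —
and a credibility index BI, the fraction of detected edge pixels lying
within Chebyshev distance 1 of a true edge pixel.

Diagnostic scores from per-pixel confusion counts: accuracy,
sensitivity, specificity and the Dice similarity coefficient
2TP / (2TP + FN + FP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "QualityReport",
    "mse",
    "psnr",
    "fom",
    "ssim",
    "edge_continuity",
    "edge_credibility",
    "confusion",
    "diagnostic_scores",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_CI_CAP = 1.0 - 1e-9  # CI is defined on [0, 1)

PRATT_RHO = 1.0 / 9.0  # standard Pratt FOM distance scaling


def _pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(reference, test) -> float:
    """Mean squared pixel difference (symmetric)."""
    a, b = _pair(reference, test)
    return float(np.mean((a - b) ** 2))


def psnr(reference, test, pe_max: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if pe_max <= 0:
        raise ValueError("pe_max must be > 0")
    err = mse(reference, test)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(pe_max**2 / err)


def fom(detected, ideal, rho: float = PRATT_RHO) -> float:
    """Pratt figure of merit in [0, 1].

    FOM = 1/max(n_detected, n_ideal) * sum over detected edge pixels of
    1 / (1 + rho * d^2), with d the Euclidean distance to the nearest
    ideal edge pixel.
    """
    d_map, i_map = _pair(detected, ideal)
    det = d_map > 0
    ide = i_map > 0
    n_ideal = int(ide.sum())
    if n_ideal == 0:
        raise ValueError("ideal edge map is empty")
    n_det = int(det.sum())
    if n_det == 0:
        return 0.0
    dist = ndimage.distance_transform_edt(~ide)
    d = dist[det]
    return float(np.sum(1.0 / (1.0 + rho * d**2)) / max(n_det, n_ideal))


def ssim(
    reference,
    test,
    pe_max: float = 1.0,
    window: int = 8,
    k1: float = 0.01,
    k2: float = 0.03,
    exponents: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Mean structural similarity over sliding windows (unit stride).

    Per window: brightness^alpha * contrast^beta * structure^gamma with
    stabilizing constants C1=(k1 L)^2, C2=(k2 L)^2, C3=C2/2 and L =
    ``pe_max``; population (ddof=0) statistics.  Default exponents are
    all 1, which reduces to the standard SSIM formula.
    """
    a, b = _pair(reference, test)
    if min(a.shape) < window:
        raise ValueError(f"image smaller than the {window}x{window} SSIM window")
    c1 = (k1 * pe_max) ** 2
    c2 = (k2 * pe_max) ** 2
    c3 = c2 / 2.0
    alpha, beta, gamma = exponents

    wa = np.lib.stride_tricks.sliding_window_view(a, (window, window))
    wb = np.lib.stride_tricks.sliding_window_view(b, (window, window))
    mu_a = wa.mean(axis=(-2, -1))
    mu_b = wb.mean(axis=(-2, -1))
    var_a = (wa**2).mean(axis=(-2, -1)) - mu_a**2
    var_b = (wb**2).mean(axis=(-2, -1)) - mu_b**2
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    sd_a = np.sqrt(var_a)
    sd_b = np.sqrt(var_b)
    cov = (wa * wb).mean(axis=(-2, -1)) - mu_a * mu_b

    bri = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    con = (2 * sd_a * sd_b + c2) / (var_a + var_b + c2)
    struct = (cov + c3) / (sd_a * sd_b + c3)
    per_window = (
        np.sign(bri) * np.abs(bri) ** alpha
        * np.abs(con) ** beta
        * np.sign(struct) * np.abs(struct) ** gamma
    )
    return float(per_window.mean())


def edge_continuity(edges) -> float:
    """Size-weighted continuity index CI in [0, 1).

    Edge segments are 8-connected components; a segment's score is the
    fraction of its pixels having >= 2 edge neighbors (within the
    segment), so open curve endpoints and isolated pixels lower it.
    Empty map -> 0.
    """
    e = np.asarray(edges).astype(bool)
    if not e.any():
        return 0.0
    neighbor_count = ndimage.convolve(
        e.astype(int), _EIGHT.astype(int), mode="constant", cval=0
    ) - e.astype(int)
    well_connected = e & (neighbor_count >= 2)
    # components are 8-connected, so any adjacent edge pixel shares the
    # segment; a global count therefore equals the per-segment count
    labels, n = ndimage.label(e, structure=_EIGHT)
    seg_sizes = np.bincount(labels.ravel())[1:]
    seg_good = np.bincount(labels.ravel(), weights=well_connected.ravel())[1:]
    ci = float(seg_good.sum() / seg_sizes.sum())
    return min(ci, _CI_CAP)


def edge_credibility(detected, truth) -> float:
    """Fraction of detected edge pixels within Chebyshev distance 1 of a
    true edge pixel; empty detected map -> 0."""
    d, t = _pair(detected, truth)
    det = d > 0
    n = int(det.sum())
    if n == 0:
        return 0.0
    near_truth = ndimage.binary_dilation(t > 0, structure=_EIGHT)
    return float(np.sum(det & near_truth) / n)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel confusion counts of a binary segmentation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred_mask, truth_mask) -> ConfusionCounts:
    """Pixelwise confusion counts; inputs must be binary (0/1)."""
    p, t = _pair(pred_mask, truth_mask)
    for name, m in (("pred", p), ("truth", t)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def diagnostic_scores(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, Dice); NaN when a
    denominator is zero."""

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    acc = ratio(c.tp + c.tn, c.total)
    sen = ratio(c.tp, c.tp + c.fn)
    spe = ratio(c.tn, c.tn + c.fp)
    dsc = ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)
    return acc, sen, spe, dsc


@dataclass
class QualityReport:
    """One evaluation record; PSNR +inf serializes as null."""

    psnr: float
    mse: float
    fom: float
    ssim: float
    ci: float
    bi: float
    acc: float = math.nan
    sen: float = math.nan
    spe: float = math.nan
    dsc: float = math.nan

    def to_dict(self) -> dict:
        def clean(v):
            if v is None or math.isnan(v):
                return None
            if math.isinf(v):
                return None
            return float(v)

        return {k: clean(v) for k, v in vars(self).items()}
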