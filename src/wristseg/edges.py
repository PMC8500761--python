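"""From-scratch Canny edge detection.

The classic four-stage detector: isotropic Gaussian smoothing, gradient
field by finite differences, non-maximum suppression along the quantized
gradient direction, and double-threshold hysteresis linking in which weak
responses (between the low and high threshold) survive only when they are
8-connected to a strong response.

Conventions (fixed repo-wide):

* row-major arrays, origin top-left; ``x`` is the column axis, ``y`` the
  row axis, so ``gx`` is the derivative across columns and ``gy`` across
  rows.
* Gaussian kernel truncated at radius ``ceil(3 sigma)`` and renormalized
  to unit sum; borders reflect-padded.
* gradients: central differences in the interior, one-sided at borders.
* NMS quantizes the direction to 4 sectors (0, 45, 90, 135 degrees, no
  sub-pixel interpolation) and keeps a pixel only if its magnitude is
  strictly greater than both directional neighbors; out-of-image
  neighbors count as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

__all__ = [
    "GradientField",
    "CannyParams",
    "CannyEdgeDetector",
    "gaussian_kernel",
    "gaussian_smooth",
    "compute_gradient",
    "nonmax_suppress",
    "hysteresis_link",
    "canny_detect",
]


def _as_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient of a smoothed image."""

    gx: np.ndarray  # d/dcol
    gy: np.ndarray  # d/drow
    magnitude: np.ndarray  # sqrt(gx^2 + gy^2)
    direction: np.ndarray  # atan2(gy, gx), in (-pi, pi]


@dataclass(frozen=True)
class CannyParams:
    """Detector parameters.

    ``low`` is the low threshold on the NMS magnitude; the high threshold
    is ``ratio * low``.  With ``relative=True`` the low threshold is a
    fraction of the maximum NMS magnitude of the image at hand (useful
    when the absolute gradient scale is unknown).  ``ratio <= 1``
    collapses the double threshold to a single threshold at ``low``.
    """

    sigma: float = 1.4
    low: float = 0.12
    ratio: float = 1.8
    relative: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.low <= 0:
            raise ValueError("low threshold must be > 0")
        if self.ratio <= 0:
            raise ValueError("threshold ratio must be > 0")


def gaussian_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Truncated, renormalized 2-D isotropic Gaussian kernel.

    The kernel is the separable product of 1-D Gaussians sampled at
    integer offsets, truncated at ``radius`` (default ``ceil(3 sigma)``)
    and rescaled to sum to exactly 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius is None:
        radius = int(np.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def gaussian_smooth(img, sigma: float, radius: int | None = None) -> np.ndarray:
    """Convolve with the renormalized truncated Gaussian, reflect-padded."""
    a = _as_image(img)
    kernel = gaussian_kernel(sigma, radius)
    return ndimage.convolve(a, kernel, mode="reflect")


def compute_gradient(img) -> GradientField:
    """Finite-difference gradient field.

    Central differences in the interior, one-sided differences on the
    first/last row and column (``np.gradient`` semantics).
    """
    a = _as_image(img)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("gradient needs an image of at least 3x3 pixels")
    gy, gx = np.gradient(a)
    magnitude = np.hypot(gx, gy)
    direction = np.arctan2(gy, gx)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, direction=direction)


# directional neighbor offsets (drow, dcol) per sector: 0deg, 45deg, 90deg, 135deg
_SECTOR_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def quantize_direction(direction: np.ndarray) -> np.ndarray:
    """Map angles to 4 sectors: 0=E-W, 1=NE-SW diagonal, 2=N-S, 3=NW-SE."""
    t = np.mod(direction, np.pi)  # fold into [0, pi)
    return np.round(t / (np.pi / 4.0)).astype(int) % 4


def nonmax_suppress(field: GradientField) -> np.ndarray:
    """Thin the magnitude image to strict directional maxima.

    A pixel keeps its magnitude only when strictly greater than both
    neighbors along the quantized gradient direction; ties are
    suppressed, so a constant field yields all zeros.
    """
    mag = field.magnitude
    h, w = mag.shape
    sectors = quantize_direction(field.direction)
    padded = np.zeros((h + 2, w + 2))
    padded[1:-1, 1:-1] = mag
    out = np.zeros_like(mag)
    for s, (dr, dc) in enumerate(_SECTOR_OFFSETS):
        sel = sectors == s
        fwd = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        bwd = padded[1 - dr : 1 - dr + h, 1 - dc : 1 - dc + w]
        keep = sel & (mag > fwd) & (mag > bwd)
        out[keep] = mag[keep]
    return out


_EIGHT = np.ones((3, 3), dtype=bool)


def hysteresis_link(nms, t_l: float, t_h: float) -> np.ndarray:
    """Double-threshold edge linking.

    A pixel is an edge iff its NMS magnitude is >= ``t_h`` (strong), or
    lies in [``t_l``, ``t_h``) (weak) and is 8-connected to a strong
    pixel through weak/strong pixels.  Pixels below ``t_l`` are never
    edges.
    """
    a = _as_image(nms)
    if not 0 < t_l <= t_h:
        raise ValueError(f"need 0 < t_l <= t_h, got t_l={t_l}, t_h={t_h}")
    candidate = a >= t_l
    strong = a >= t_h
    if not strong.any():
        return np.zeros(a.shape, dtype=np.uint8)
    labels, n = ndimage.label(candidate, structure=_EIGHT)
    seeded = np.unique(labels[strong])
    keep = np.zeros(n + 1, dtype=bool)
    keep[seeded] = True
    keep[0] = False
    return keep[labels].astype(np.uint8)


def canny_detect(img, params: CannyParams | None = None) -> np.ndarray:
    """Full Canny pipeline: smooth -> gradient -> NMS -> hysteresis.

    Returns a binary uint8 edge map.  Deterministic; an all-constant
    image (or thresholds above the maximum magnitude) yields an empty
    map.
    """
    params = params or CannyParams()
    smoothed = gaussian_smooth(img, params.sigma)
    field = compute_gradient(smoothed)
    nms = nonmax_suppress(field)
    t_l = params.low * nms.max() if params.relative else params.low
    if t_l <= 0:  # flat image: no gradient anywhere
        return np.zeros(nms.shape, dtype=np.uint8)
    t_h = params.ratio * t_l
    if t_h <= t_l:
        # degenerate ratio <= 1: the weak band is empty and the double
        # threshold collapses to a single threshold at t_l
        return (nms >= t_l).astype(np.uint8)
    return hysteresis_link(nms, t_l, t_h)


class CannyEdgeDetector(BaseEstimator):
    """Estimator-style wrapper around :func:`canny_detect`.

    Stateless (``fit`` is a no-op kept for pipeline compatibility);
    ``transform`` maps one image to its binary edge map.
    """

    def __init__(
        self,
        sigma: float = 1.4,
        low: float = 0.12,
        ratio: float = 1.8,
        relative: bool = True,
    ):
        self.sigma = sigma
        self.low = low
        self.ratio = ratio
        self.relative = relative

    def _params(self) -> CannyParams:
        return CannyParams(
            sigma=self.sigma, low=self.low, ratio=self.ratio, relative=self.relative
        )

    def fit(self, X=None, y=None):
        self._params()  # validate
        return self

    def transform(self, X) -> np.ndarray:
        return canny_detect(X, self._params())

    detect = transform
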