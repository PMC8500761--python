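"""Synthetic wrist-MRI-like phantoms with exact ground truth.

A phantom is a 2-D grayscale image built from piecewise-near-constant
regions (convex ellipses for bones, a thin crescent for cartilage, one
designated lesion region), modulated by a smooth multiplicative bias
field that emulates MRI gray-level inhomogeneity, and corrupted by
additive noise.  Because the region label image is known exactly, the
phantom carries pixel-exact ground-truth edge and lesion masks, so every
downstream stage of the segmentation pipeline can be tested without
patient data.

Coordinate convention (used repo-wide): row-major arrays, origin at the
top-left corner, 0-based indices, pixel centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Region",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "default_wrist_spec",
]


@dataclass(frozen=True)
class Region:
    """One piecewise-constant region of a phantom.

    Parameters
    ----------
    shape : {"ellipse", "crescent"}
        An ellipse is the filled set ((u/a)^2 + (v/b)^2 <= 1) in rotated
        local coordinates.  A crescent is an outer ellipse minus an inner
        ellipse whose center is offset and whose axes are shrunk, giving a
        thin curved sliver such as wrist cartilage.
    center : (row, col) in pixels.
    axes : (semi_axis_rows, semi_axis_cols) in pixels, both > 0.
    rotation : counter-clockwise rotation in radians.
    intensity : region mean gray level in [0, 1].
    inner_offset, inner_scale : crescent-only; center shift of the
        subtracted inner ellipse and its axis scale factor in (0, 1].
    """

    shape: str
    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float = 0.0
    intensity: float = 0.5
    inner_offset: tuple[float, float] = (0.0, 0.0)
    inner_scale: float = 0.9

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "crescent"):
            raise ValueError(f"unknown region shape {self.shape!r}")
        if min(self.axes) <= 0:
            raise ValueError(f"degenerate region: axes {self.axes} must be > 0")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"region intensity {self.intensity} outside [0, 1]")
        if self.shape == "crescent" and not 0.0 < self.inner_scale <= 1.0:
            raise ValueError("crescent inner_scale must be in (0, 1]")

    def mask(self, height: int, width: int) -> np.ndarray:
        """Rasterize with pixel-center point-in-shape tests."""
        rr, cc = np.mgrid[0:height, 0:width]
        inside = _ellipse_mask(rr, cc, self.center, self.axes, self.rotation)
        if self.shape == "crescent":
            inner_center = (
                self.center[0] + self.inner_offset[0],
                self.center[1] + self.inner_offset[1],
            )
            inner_axes = (
                self.axes[0] * self.inner_scale,
                self.axes[1] * self.inner_scale,
            )
            inside &= ~_ellipse_mask(rr, cc, inner_center, inner_axes, self.rotation)
        return inside


def _ellipse_mask(rr, cc, center, axes, rotation) -> np.ndarray:
    dr = rr - center[0]
    dc = cc - center[1]
    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    u = cos_t * dr + sin_t * dc
    v = -sin_t * dr + cos_t * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; deterministic given ``seed``.

    ``background`` is the gray level outside every region.  Regions are
    painted in list order (later regions overwrite earlier ones), and
    ``lesion_index`` designates which region is the lesion.  The bias
    field is a smooth second-order polynomial surface rescaled to the
    range [1 - bias_amplitude, 1 + bias_amplitude]; noise is additive
    zero-mean Gaussian by default, with a Rician option.
    """

    width: int
    height: int
    regions: tuple[Region, ...] = field(default_factory=tuple)
    lesion_index: int = 0
    background: float = 0.15
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("phantom dimensions must be >= 1 pixel")
        if not self.regions:
            raise ValueError("a phantom needs at least one region")
        if not 0 <= self.lesion_index < len(self.regions):
            raise ValueError(
                f"lesion_index {self.lesion_index} does not refer to an existing region"
            )
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.background <= 1.0:
            raise ValueError("background intensity must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "background": self.background,
            "bias_amplitude": self.bias_amplitude,
            "noise_sigma": self.noise_sigma,
            "noise_model": self.noise_model,
            "seed": self.seed,
            "lesion_index": self.lesion_index,
            "regions": [
                {
                    "shape": r.shape,
                    "center": list(r.center),
                    "axes": list(r.axes),
                    "rotation": r.rotation,
                    "intensity": r.intensity,
                    "inner_offset": list(r.inner_offset),
                    "inner_scale": r.inner_scale,
                }
                for r in self.regions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        regions = tuple(
            Region(
                shape=r["shape"],
                center=tuple(r["center"]),
                axes=tuple(r["axes"]),
                rotation=r.get("rotation", 0.0),
                intensity=r.get("intensity", 0.5),
                inner_offset=tuple(r.get("inner_offset", (0.0, 0.0))),
                inner_scale=r.get("inner_scale", 0.9),
            )
            for r in d["regions"]
        )
        return cls(
            width=d["width"],
            height=d["height"],
            regions=regions,
            lesion_index=d.get("lesion_index", 0),
            background=d.get("background", 0.15),
            bias_amplitude=d.get("bias_amplitude", 0.0),
            noise_sigma=d.get("noise_sigma", 0.0),
            noise_model=d.get("noise_model", "gaussian"),
            seed=d.get("seed", 0),
        )


@dataclass(frozen=True)
class Phantom:
    """A generated phantom and its exact ground truth."""

    image: np.ndarray  # H x W floats in [0, 1]
    noiseless: np.ndarray  # same, before the noise stage (bias included)
    labels: np.ndarray  # H x W int region labels; 0 = background
    truth_edges: np.ndarray  # H x W uint8; label differs from a 4-neighbor
    lesion_mask: np.ndarray  # H x W uint8
    spec: PhantomSpec


def _label_image(spec: PhantomSpec) -> np.ndarray:
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    for i, region in enumerate(spec.regions, start=1):
        labels[region.mask(spec.height, spec.width)] = i
    return labels


def _boundary_from_labels(labels: np.ndarray) -> np.ndarray:
    """Pixels whose region label differs from at least one 4-neighbor."""
    edges = np.zeros(labels.shape, dtype=bool)
    diff_r = labels[1:, :] != labels[:-1, :]
    diff_c = labels[:, 1:] != labels[:, :-1]
    edges[1:, :] |= diff_r
    edges[:-1, :] |= diff_r
    edges[:, 1:] |= diff_c
    edges[:, :-1] |= diff_c
    return edges


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth second-order 2-D polynomial surface in [1-A, 1+A]."""
    if spec.bias_amplitude == 0:
        return np.ones((spec.height, spec.width))
    # normalized coordinates in [-1, 1]
    r = np.linspace(-1.0, 1.0, spec.height)[:, None]
    c = np.linspace(-1.0, 1.0, spec.width)[None, :]
    coef = rng.uniform(-1.0, 1.0, size=6)
    surface = (
        coef[0] * r
        + coef[1] * c
        + coef[2] * r * c
        + coef[3] * r**2
        + coef[4] * c**2
        + coef[5]
    )
    lo, hi = surface.min(), surface.max()
    if hi - lo < 1e-12:  # degenerate draw: flat surface
        return np.ones_like(surface)
    unit = (surface - lo) / (hi - lo)  # [0, 1]
    return 1.0 - spec.bias_amplitude + 2.0 * spec.bias_amplitude * unit


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom: region means x bias field + noise, clipped to [0, 1].

    Ground-truth edge and lesion masks are derived from the noiseless
    label image, so they are exact regardless of noise level.  The result
    is bit-identical for identical specs (the seed drives both the bias
    coefficients and the noise draw through independent substreams).
    """
    labels = _label_image(spec)
    means = np.concatenate(
        ([spec.background], [r.intensity for r in spec.regions])
    )
    piecewise = means[labels]

    ss = np.random.SeedSequence(spec.seed)
    bias_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    noiseless = np.clip(piecewise * _bias_field(spec, bias_rng), 0.0, 1.0)

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            noisy = noiseless + noise_rng.normal(
                0.0, spec.noise_sigma, size=noiseless.shape
            )
        else:  # rician: magnitude of complex signal with iid Gaussian parts
            n1 = noise_rng.normal(0.0, spec.noise_sigma, size=noiseless.shape)
            n2 = noise_rng.normal(0.0, spec.noise_sigma, size=noiseless.shape)
            noisy = np.hypot(noiseless + n1, n2)
        image = np.clip(noisy, 0.0, 1.0)
    else:
        image = noiseless.copy()

    truth_edges = _boundary_from_labels(labels).astype(np.uint8)
    lesion_mask = (labels == spec.lesion_index + 1).astype(np.uint8)
    return Phantom(
        image=image,
        noiseless=noiseless,
        labels=labels,
        truth_edges=truth_edges,
        lesion_mask=lesion_mask,
        spec=spec,
    )


def default_wrist_spec(
    seed: int,
    size: int = 128,
    noise_sigma: float = 0.03,
    bias_amplitude: float = 0.08,
    lesion_contrast: float = 0.28,
) -> PhantomSpec:
    """Wrist-like phantom: three gray-similar bones, thin cartilage crescent,
    and one higher-signal lesion inside the distal radius.

    The bone gray levels are deliberately within 0.1 of each other,
    mimicking the near-identical signal of the radius, scaphoid and
    lunate on wrist MRI; the cartilage crescent is thin (well under a
    tenth of the image width); the lesion mean sits ``lesion_contrast``
    above its host bone.  Geometry is jittered slightly per seed so a
    cohort of phantoms is not a single repeated image.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x77)))
    s = size / 128.0  # geometry designed on a 128 px canvas

    def jit(scale=2.0):
        return float(rng.uniform(-scale, scale)) * s

    radius_mean = 0.62
    radius = Region(
        "ellipse",
        center=(94 * s + jit(), 64 * s + jit()),
        axes=(26 * s, 42 * s),
        rotation=rng.uniform(-0.08, 0.08),
        intensity=radius_mean,
    )
    scaphoid = Region(
        "ellipse",
        center=(38 * s + jit(), 38 * s + jit()),
        axes=(13 * s, 11 * s),
        rotation=0.4 + rng.uniform(-0.1, 0.1),
        intensity=0.58,
    )
    lunate = Region(
        "ellipse",
        center=(36 * s + jit(), 90 * s + jit()),
        axes=(12 * s, 11 * s),
        rotation=-0.3 + rng.uniform(-0.1, 0.1),
        intensity=0.66,
    )
    cartilage = Region(
        "crescent",
        center=(52 * s + jit(1.0), 64 * s + jit(1.0)),
        axes=(16 * s, 34 * s),
        rotation=rng.uniform(-0.05, 0.05),
        intensity=0.50,
        inner_offset=(-3.5 * s, 0.0),
        inner_scale=0.88,
    )
    lesion = Region(
        "ellipse",
        center=(95 * s + jit(), 50 * s + jit()),
        axes=(9 * s, 12 * s),
        rotation=0.3 + rng.uniform(-0.2, 0.2),
        intensity=min(1.0, radius_mean + lesion_contrast),
    )
    regions = (radius, scaphoid, lunate, cartilage, lesion)
    return PhantomSpec(
        width=size,
        height=size,
        regions=regions,
        lesion_index=len(regions) - 1,
        background=0.15,
        bias_amplitude=bias_amplitude,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def noiseless_spec(spec: PhantomSpec) -> PhantomSpec:
    """The same phantom recipe with noise and bias switched off."""
    return replace(spec, noise_sigma=0.0, bias_amplitude=0.0)
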