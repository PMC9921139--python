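"""Synthetic two-domain echocardiography-like phantoms.

Each phantom is a sector-scan style grayscale image containing a nested
pair of structures: an elliptical blood pool (endocardium) surrounded by
a brighter myocardial annulus (epicardium).  Speckle is modelled as
multiplicative gamma-distributed noise on a smooth tissue template — the
standard desk-scale surrogate for fully developed ultrasound speckle.

Two configurations that differ only in *style* parameters (intensity
gamma, speckle shape, background texture scale) share the same geometry
stream, so they define a pure appearance shift between two acquisition
"domains" with an identical distribution of mask shapes.  This is the
controlled stand-in for the cross-vendor distribution shift that
degrades a segmentation network trained on one scanner and applied to
another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage


@dataclass
class PhantomConfig:
    """Generation parameters for one synthetic domain.

    Geometry parameters (``endo_axis_range`` as a fraction of image
    width, ``epi_margin_range`` in pixels, ``cone_angle`` in degrees)
    control mask shapes; style parameters (``gamma``, ``speckle_shape``,
    ``texture_scale``) control appearance only.
    """

    image_size: int = 256
    n_images: int = 16
    domain: str = "A"
    endo_axis_range: tuple[float, float] = (0.12, 0.20)
    epi_margin_range: tuple[int, int] = (4, 10)
    cone_angle: float = 75.0
    speckle_shape: float = 4.0
    gamma: float = 1.0
    texture_scale: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.endo_axis_range
        mlo, mhi = self.epi_margin_range
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not (0 < lo <= hi):
            raise ValueError(f"invalid endo_axis_range {self.endo_axis_range}")
        if not (1 <= mlo <= mhi):
            raise ValueError(f"invalid epi_margin_range {self.epi_margin_range}")
        # worst case: ellipse at max jitter plus the epicardial margin must fit
        max_extent = hi * self.image_size + mhi
        if 0.65 * self.image_size + max_extent >= self.image_size:
            raise ValueError(
                "epicardial annulus would exceed the image: shrink endo_axis_range "
                "or epi_margin_range for image_size "
                f"{self.image_size}")


@dataclass
class ImageSample:
    """One grayscale image with optional nested masks and a boundary target."""

    image: np.ndarray
    endo_mask: Optional[np.ndarray] = None
    epi_mask: Optional[np.ndarray] = None
    boundary_map: Optional[np.ndarray] = None
    domain: str = "source"
    spacing: float = 1.0

    def __post_init__(self) -> None:
        for m in (self.endo_mask, self.epi_mask, self.boundary_map):
            if m is not None and m.shape != self.image.shape:
                raise ValueError("mask/boundary shape differs from image shape")
        if self.endo_mask is not None and self.epi_mask is not None:
            if np.any(self.endo_mask & ~self.epi_mask):
                raise ValueError("endocardium mask is not contained in epicardium mask")

    @property
    def labeled(self) -> bool:
        return self.endo_mask is not None and self.epi_mask is not None

    def as_unlabeled(self) -> "ImageSample":
        """Copy with annotations dropped (an unlabeled target-domain sample)."""
        return ImageSample(image=self.image, domain=self.domain, spacing=self.spacing)


def boundary_from_mask(mask: np.ndarray, width: int = 2) -> np.ndarray:
    """Contour band of a binary mask as a float map in {0, 1}.

    The band is ``dilate(mask, width//2) & ~erode(mask, ceil(width/2))``
    with a 3x3 square structuring element, i.e. a morphological gradient
    band of total thickness ``width`` straddling the mask contour
    (width 1 reduces to the inner contour).  An empty mask yields an
    all-zero map.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.float32)
    n_out = width // 2
    n_in = width - n_out
    dil = ndimage.binary_dilation(mask, np.ones((3, 3)), iterations=n_out) if n_out else mask
    ero = ndimage.binary_erosion(mask, np.ones((3, 3)), iterations=n_in)
    return (dil & ~ero).astype(np.float32)


def _sector_mask(size: int, cone_angle: float) -> np.ndarray:
    """Ultrasound sector: apex at top-centre, opening downward."""
    if cone_angle >= 360.0:
        return np.ones((size, size), dtype=bool)
    rows, cols = np.mgrid[0:size, 0:size]
    dy = rows.astype(np.float64)
    dx = cols.astype(np.float64) - (size - 1) / 2.0
    half = np.deg2rad(cone_angle / 2.0)
    angle = np.arctan2(np.abs(dx), dy + 1e-9)
    radius = np.hypot(dx, dy)
    return (angle <= half) & (radius <= 0.98 * size)


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size]
    y = rows - cy
    x = cols - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _smooth_noise(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Zero-mean unit-ish amplitude texture with correlation length `scale`."""
    field_ = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=max(scale, 1e-6))
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_sample(config: PhantomConfig, geom_rng: np.random.Generator,
                    style_rng: np.random.Generator,
                    boundary_width: int = 2) -> ImageSample:
    """Draw one phantom.

    Geometry and style consume independent RNG streams, so two configs
    that differ only in style parameters produce identical mask shapes
    from the same seed (the gamma speckle draw uses rejection sampling,
    whose stream consumption depends on the shape parameter).
    """
    s = config.image_size
    lo, hi = config.endo_axis_range
    a = geom_rng.uniform(lo, hi) * s
    b = geom_rng.uniform(lo, hi) * s
    theta = geom_rng.uniform(0.0, np.pi)
    cy = s * geom_rng.uniform(0.50, 0.62)
    cx = s * geom_rng.uniform(0.44, 0.56)
    margin = int(round(geom_rng.uniform(*config.epi_margin_range)))
    texture = _smooth_noise(style_rng, s, config.texture_scale)
    speckle = style_rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape,
                              size=(s, s))

    cone = _sector_mask(s, config.cone_angle)
    endo = _ellipse_mask(s, cy, cx, a, b, theta) & cone
    epi = ndimage.binary_dilation(endo, ndimage.generate_binary_structure(2, 2),
                                  iterations=margin) & cone

    template = np.full((s, s), 0.30)
    template += 0.12 * texture
    template[epi & ~endo] = 0.78
    template[endo] = 0.10
    template = ndimage.gaussian_filter(template, sigma=1.0)
    img = np.clip(template * speckle, 0.0, 1.0) ** config.gamma
    img[~cone] = 0.0

    boundary = np.maximum(boundary_from_mask(endo, boundary_width),
                          boundary_from_mask(epi, boundary_width))
    return ImageSample(image=img.astype(np.float32), endo_mask=endo, epi_mask=epi,
                       boundary_map=boundary, domain=config.domain)


def generate_dataset(config: PhantomConfig, boundary_width: int = 2) -> list[ImageSample]:
    """Generate ``config.n_images`` phantoms, deterministic in ``config.seed``."""
    config.validate()
    geom_rng = np.random.default_rng([config.seed, 0])
    style_rng = np.random.default_rng([config.seed, 1])
    return [generate_sample(config, geom_rng, style_rng, boundary_width)
            for _ in range(config.n_images)]


def style_shifted(config: PhantomConfig, *, gamma: float | None = None,
                  speckle_shape: float | None = None,
                  texture_scale: float | None = None,
                  domain: str | None = None) -> PhantomConfig:
    """A copy of `config` with only style (appearance) parameters changed."""
    kwargs = {}
    if gamma is not None:
        kwargs["gamma"] = gamma
    if speckle_shape is not None:
        kwargs["speckle_shape"] = speckle_shape
    if texture_scale is not None:
        kwargs["texture_scale"] = texture_scale
    if domain is not None:
        kwargs["domain"] = domain
    return replace(config, **kwargs)
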