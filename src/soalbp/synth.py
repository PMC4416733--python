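"""Synthetic textures with controllable dominant scale and orientation.

The generator emulates the material-texture imagery the method is aimed
at: gray-level patches with one dominant spatial scale (blob-like
band-pass structure) and, for the anisotropic kinds, one dominant
orientation.  The construction is calibrated so that the package's own
estimators are unbiased on it: ``dominant_scale`` is the characteristic
scale at which the summed scale-normalized Laplacian response of the
texture peaks, and ``dominant_orientation`` is the angle (radians in
[0, pi), measured from the vertical image axis) that the structure-tensor
orientation estimator reports.

For Gaussian-correlated noise the expected response profile is
``sigma^2 * (sigma_f^2 + sigma^2)^(-3/2)`` for filter width ``sigma_f``,
which peaks at ``sigma = sqrt(2) * sigma_f``; the blob generator therefore
filters white noise with ``dominant_scale / sqrt(2)``.  The grating's
summed response is ``sigma^2 * exp(-(2 pi f sigma)^2 / 2)``, peaking at
``sigma = sqrt(2) / (2 pi f)``; its spatial wavelength is set accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize, rotate

__all__ = ["TextureSpec", "make_texture", "transform"]

KINDS = ("blobs", "grating", "oriented-noise")

#: Elongation of the oriented-noise kind: smoothing along the dominant axis
#: is this many times stronger than across it.
ANISOTROPY = 8.0


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one synthetic texture patch."""

    kind: str = "blobs"
    dominant_scale: float = 4.0
    dominant_orientation: float = 0.0  # radians, from the vertical axis
    size: int = 128
    contrast: float = 1.0
    noise: float = 0.002  # additive white sensor noise, fraction of the 8-bit range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.dominant_scale <= 0:
            raise ValueError("dominant_scale must be positive")
        if self.size < 128:
            raise ValueError("size must be at least 128")


def _to_uint8_range(field: np.ndarray, contrast: float) -> np.ndarray:
    field = field - field.mean()
    sd = field.std()
    if sd > 0:
        field = field / sd
    out = 128.0 + contrast * 40.0 * field
    return np.clip(out, 0.0, 255.0)


def make_texture(spec: TextureSpec) -> np.ndarray:
    """Render the texture described by ``spec`` (float image in [0, 255]).

    Deterministic given the seed: the same spec always yields a
    bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    pad = int(np.ceil(4 * spec.dominant_scale))
    big = n + 2 * pad

    if spec.kind == "blobs":
        field = ndimage.gaussian_filter(
            rng.standard_normal((big, big)),
            spec.dominant_scale / np.sqrt(2.0),
            mode="wrap",
        )
        field = field[pad : pad + n, pad : pad + n]
    elif spec.kind == "grating":
        # wavelength chosen so the response profile peaks at dominant_scale
        wavelength = np.sqrt(2.0) * np.pi * spec.dominant_scale
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        # phase varies along the dominant-gradient direction; at orientation 0
        # the gradient is vertical (structures horizontal)
        o = spec.dominant_orientation
        coord = yy * np.cos(o) + xx * np.sin(o)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        field = np.sin(2.0 * np.pi * coord / wavelength + phase)
    else:  # oriented-noise
        # elongate along the structure axis, band-limit across it, then
        # rotate into place on an oversized canvas to avoid border effects
        rot_pad = int(np.ceil(big * (np.sqrt(2.0) - 1.0) / 2.0)) + 2
        canvas = big + 2 * rot_pad
        across = spec.dominant_scale / np.sqrt(2.0)
        base = ndimage.gaussian_filter(
            rng.standard_normal((canvas, canvas)),
            (across, ANISOTROPY * across),  # (y, x): elongated along x
            mode="wrap",
        )
        deg = np.degrees(spec.dominant_orientation)
        field = rotate(base, deg, order=1, mode="reflect")
        c0 = (canvas - n) // 2
        field = field[c0 : c0 + n, c0 : c0 + n]

    if spec.noise > 0:
        field = _to_uint8_range(field, spec.contrast)
        field = field + spec.noise * 255.0 * rng.standard_normal(field.shape)
        return np.clip(field, 0.0, 255.0)
    return _to_uint8_range(field, spec.contrast)


def transform(
    image: np.ndarray,
    scale_factor: float = 1.0,
    rotation_deg: float = 0.0,
    crop: int = 128,
) -> np.ndarray:
    """Rescale, rotate about the center, and center-crop a texture patch.

    Emulates how evaluation sets at probe scales are built from larger
    source images: resampling by ``scale_factor`` (anti-aliased for
    shrinking, bilinear for magnification), rotation by ``rotation_deg``
    counter-clockwise, then a central ``crop x crop`` cut.
    """
    if scale_factor <= 0:
        raise ValueError("scale factor must be positive")
    image = np.asarray(image, dtype=np.float64)
    if scale_factor != 1.0:
        shape = (
            max(1, int(round(image.shape[0] * scale_factor))),
            max(1, int(round(image.shape[1] * scale_factor))),
        )
        image = resize(
            image,
            shape,
            order=1,
            anti_aliasing=scale_factor < 1.0,
            mode="reflect",
            preserve_range=True,
        )
    if rotation_deg != 0.0:
        image = rotate(image, rotation_deg, order=1, mode="reflect", preserve_range=True)
    h, w = image.shape
    if h < crop or w < crop:
        raise ValueError("transformed image smaller than the crop size")
    y0, x0 = (h - crop) // 2, (w - crop) // 2
    return image[y0 : y0 + crop, x0 : x0 + crop]
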