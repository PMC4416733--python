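"""Standard, scale-adaptive and scale+orientation-adaptive LBP extraction.

A Local Binary Pattern encodes, per pixel, the signs of intensity
differences between the center and ``n`` equidistant neighbors on a circle.
The scale-adaptive variant replaces the fixed radius by the intrinsic-scale
adapted radius ``lambda = rho * s / s_bar_l`` and low-pass filters the image
first so that every neighbor samples a support area matched to that radius.
The orientation-adaptive variant additionally rotates the sampling circle
to the estimated global orientation, accumulating patterns over a small
interval of orientation offsets to compensate estimation errors, and over
the two antipodal start orientations ``o`` and ``o + pi`` (the structure
tensor cannot distinguish them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import erf, erfinv

from .base_scales import TrainedBaseScales, adapted_radius
from .scalespace import ScaleEstimate

__all__ = [
    "SamplingKernel",
    "PatternHistogram",
    "standard_lbp",
    "sampling_kernel",
    "filter_image",
    "adaptive_threshold",
    "extract_sa_lbp",
    "extract_soa_lbp",
]


@dataclass(frozen=True)
class SamplingKernel:
    """1-D separable Gaussian sampling filter built from integrated bins.

    The kernel radius ``gr = lambda * pi / n`` is the half-arc between two
    neighbors on the sampling circle; ``sigma_g`` is chosen so that a
    fraction ``P`` (default 0.99) of the Gaussian mass falls inside
    ``[-gr, gr]``.  Weights are exact integrals of the Gaussian over unit
    pixel bins (via erf), which is stabler than point-sampling a narrow
    Gaussian.
    """

    gr: float
    sigma_g: float
    weights: np.ndarray

    @property
    def is_identity(self) -> bool:
        return len(self.weights) == 1


@dataclass
class PatternHistogram:
    """Normalized distribution of LBP codes with its extraction context."""

    bins: np.ndarray
    class_ref: object = None
    base_radius: float | None = None
    adapted_radius: float | None = None
    fallback: bool = False

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        total = self.bins.sum()
        if total <= 0:
            raise ValueError("empty pattern histogram")
        if abs(total - 1.0) > 1e-9:
            self.bins = self.bins / total

    @property
    def n_neighbors(self) -> int:
        return int(round(np.log2(len(self.bins))))


def _neighbor_offsets(radius: float, n: int, orientation: float = 0.0) -> list[tuple[float, float]]:
    """(dx, dy) offsets of the n neighbors; x right, y down, CCW in math sense."""
    out = []
    for k in range(n):
        ang = orientation + 2.0 * np.pi * k / n
        out.append((radius * np.cos(ang), -radius * np.sin(ang)))
    return out


def _bilinear_shift(image: np.ndarray, dx: float, dy: float, ys: slice, xs: slice) -> np.ndarray:
    """Sample image at (x+dx, y+dy) for the interior window via bilinear weights.

    Because the offset is constant across pixels, the interpolation reduces
    to a weighted sum of four integer-shifted views, which is much faster
    than generic coordinate mapping.
    """
    # snap near-integer offsets so that exact lattice neighbors are read
    # directly instead of through lossy interpolation arithmetic
    if abs(dx - round(dx)) < 1e-9:
        dx = round(dx)
    if abs(dy - round(dy)) < 1e-9:
        dy = round(dy)
    fx, fy = int(np.floor(dx)), int(np.floor(dy))
    wx, wy = dx - fx, dy - fy
    y0, y1 = ys.start + fy, ys.stop + fy
    x0, x1 = xs.start + fx, xs.stop + fx

    def block(oy: int, ox: int) -> np.ndarray:
        return image[y0 + oy : y1 + oy, x0 + ox : x1 + ox]

    b00, b01, b10, b11 = block(0, 0), block(0, 1), block(1, 0), block(1, 1)
    # factored form: exact on lattice points and exactly constant-preserving
    return b00 + wx * (b01 - b00) + wy * (b10 - b00) + wx * wy * (b11 - b10 - b01 + b00)


def lbp_codes(
    image: np.ndarray,
    radius: float,
    n: int = 8,
    threshold: float = 0.0,
    orientation: float = 0.0,
) -> np.ndarray:
    """LBP code per interior pixel (bilinearly interpolated neighbors).

    Pixels closer than ``ceil(radius) + 1`` to any border are skipped to
    avoid padding artifacts; the returned array covers the interior window
    only.
    """
    image = np.asarray(image, dtype=np.float64)
    if n < 4:
        raise ValueError("need at least 4 neighbors")
    if radius <= 0:
        raise ValueError("radius must be positive")
    margin = int(np.ceil(radius)) + 1
    h, w = image.shape
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("image too small for the requested radius")
    ys, xs = slice(margin, h - margin), slice(margin, w - margin)
    center = image[ys, xs]
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (dx, dy) in enumerate(_neighbor_offsets(radius, n, orientation)):
        sampled = _bilinear_shift(image, dx, dy, ys, xs)
        codes += (1 << k) * (sampled - center >= threshold)
    return codes


def _histogram(codes: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(codes.ravel(), minlength=1 << n).astype(np.float64)


def standard_lbp(
    image: np.ndarray,
    radius: float,
    n: int = 8,
    threshold: float = 0.0,
    orientation: float = 0.0,
) -> PatternHistogram:
    """Plain LBP histogram at a fixed radius (no filtering, no adaption)."""
    if radius < 1:
        raise ValueError("radius must be at least 1 for discriminative patterns")
    counts = _histogram(lbp_codes(image, radius, n, threshold, orientation), n)
    return PatternHistogram(bins=counts / counts.sum(), adapted_radius=radius)


def sampling_kernel(lam: float, n: int = 8, P: float = 0.99) -> SamplingKernel:
    """Separable Gaussian sampling filter for adapted radius ``lam``.

    ``gr = lam * pi / n``; ``sigma_g = gr / (sqrt(2) * erfinv(P))`` so that a
    fraction P of the Gaussian mass lies within ``[-gr, gr]``; the discrete
    weights integrate the Gaussian over each unit pixel bin and are
    normalized to sum to one.
    """
    if lam <= 0:
        raise ValueError("radius must be positive")
    gr = lam * np.pi / n
    sigma_g = gr / (np.sqrt(2.0) * erfinv(P))
    r = int(np.ceil(gr))
    x = np.arange(-r, r + 1, dtype=np.float64)
    denom = np.sqrt(2.0) * sigma_g
    w = erf((x + 0.5) / denom) - erf((x - 0.5) / denom)
    w /= w.sum()
    return SamplingKernel(gr=gr, sigma_g=sigma_g, weights=w)


def filter_image(image: np.ndarray, kernel: SamplingKernel) -> np.ndarray:
    """Apply the sampling kernel as a separable convolution (reflect borders)."""
    image = np.asarray(image, dtype=np.float64)
    if kernel.is_identity:
        return image
    out = ndimage.correlate1d(image, kernel.weights, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kernel.weights, axis=1, mode="reflect")


def adaptive_threshold(filtered_image: np.ndarray) -> float:
    """Sign threshold for orientation-adaptive patterns.

    The square root of the (population) standard deviation of the filtered
    image; damps bit fluctuation from interpolation artifacts while scaling
    with image contrast.
    """
    filtered_image = np.asarray(filtered_image, dtype=np.float64)
    if filtered_image.size == 0:
        raise ValueError("empty image")
    return float(np.sqrt(filtered_image.std()))


def extract_sa_lbp(
    image: np.ndarray,
    class_ref: object,
    scale: ScaleEstimate,
    rho: float,
    base: TrainedBaseScales,
    n: int = 8,
    threshold: float = 0.0,
    filtered: np.ndarray | None = None,
) -> PatternHistogram:
    """Scale-adaptive LBP histogram in reference to one trained base scale.

    The image is convolved with the separable sampling kernel for the
    adapted radius ``lambda(s, l, rho)`` and patterns are computed at that
    radius.  ``filtered`` short-circuits the filtering when the caller has
    cached it for this radius.
    """
    if not scale.valid:
        raise ValueError("scale estimate invalid; caller must use the fallback path")
    lam = adapted_radius(scale.s, class_ref, rho, base)
    if filtered is None:
        filtered = filter_image(image, sampling_kernel(lam, n))
    counts = _histogram(lbp_codes(filtered, lam, n, threshold), n)
    return PatternHistogram(
        bins=counts / counts.sum(),
        class_ref=class_ref,
        base_radius=rho,
        adapted_radius=lam,
    )


def extract_soa_lbp(
    image: np.ndarray,
    class_ref: object,
    scale: ScaleEstimate,
    orientation: float,
    rho: float,
    base: TrainedBaseScales,
    n: int = 8,
    delta_o_deg: float = 20.0,
    step_deg: float = 5.0,
    threshold: float | None = None,
    dual_orientation: bool = True,
    filtered: np.ndarray | None = None,
) -> PatternHistogram:
    """Scale- and orientation-adaptive LBP histogram.

    Pattern counts are accumulated over orientation offsets
    ``{o - delta_o, ..., o + delta_o}`` in ``step_deg`` steps (compensating
    orientation-estimation errors up to ``delta_o``), and, because the
    structure-tensor orientation is ambiguous by pi, over both start
    orientations ``o`` and ``o + pi`` when ``dual_orientation`` is set.  The
    sign threshold defaults to ``adaptive_threshold`` of the filtered image.
    """
    if not scale.valid:
        raise ValueError("scale estimate invalid; caller must use the fallback path")
    lam = adapted_radius(scale.s, class_ref, rho, base)
    if filtered is None:
        filtered = filter_image(image, sampling_kernel(lam, n))
    if threshold is None:
        threshold = adaptive_threshold(filtered)

    if delta_o_deg > 0:
        n_side = int(round(delta_o_deg / step_deg))
        offsets_deg = (np.arange(-n_side, n_side + 1) * step_deg)
    else:
        offsets_deg = np.array([0.0])
    starts = (orientation, orientation + np.pi) if dual_orientation else (orientation,)

    counts = np.zeros(1 << n, dtype=np.float64)
    for start in starts:
        for off in np.radians(offsets_deg):
            counts += _histogram(lbp_codes(filtered, lam, n, threshold, start + off), n)
    return PatternHistogram(
        bins=counts / counts.sum(),
        class_ref=class_ref,
        base_radius=rho,
        adapted_radius=lam,
    )
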