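"""Gaussian scale-space construction and global scale estimation.

The global scale of a texture image is estimated from the distribution of
scale-normalized Laplacian responses across a Gaussian scale-space.  For
each scale level the absolute scale-normalized Laplacian is summed over
the image, yielding a response profile over scale.  The first local
maximum of that profile seeds a least-squares Gaussian fit whose mean is
the dominant (fractional) scale level and whose standard deviation acts
as an uncertainty measure: estimates with a large uncertainty are flagged
invalid so that downstream feature extraction can fall back to
fixed-radius patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy import ndimage
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "ScaleGrid",
    "ScaleSpace",
    "ScaleEstimate",
    "build_scale_space",
    "normalized_laplacian",
    "scale_response",
    "estimate_global_scale",
    "estimate_scale",
]

#: Default scaling factor of the exponential scale grid.  Chosen so that the
#: spatial extent (sigma * sqrt(2)) of the level at exponent k = 0 matches an
#: LBP radius of 3 pixels.
DEFAULT_C = 2.1214

MIN_IMAGE_SIDE = 16


@dataclass(frozen=True)
class ScaleGrid:
    """Exponentially spaced grid of Gaussian standard deviations.

    The grid is ``sigma_i = c * 2**k_i`` with exponents ``k_i`` running from
    ``k_min`` to ``k_max`` in steps of ``k_step`` (default: -4 to 8 in steps
    of 0.25, i.e. 49 levels).  Exponential spacing gives fine resolution at
    small scales while still covering the large intrinsic scales of natural
    textures.
    """

    c: float = DEFAULT_C
    k_min: float = -4.0
    k_max: float = 8.0
    k_step: float = 0.25

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("scaling factor c must be positive")
        if self.k_step <= 0 or self.k_max < self.k_min:
            raise ValueError("invalid exponent range")

    @property
    def exponents(self) -> np.ndarray:
        n = int(round((self.k_max - self.k_min) / self.k_step)) + 1
        return self.k_min + self.k_step * np.arange(n)

    @property
    def sigmas(self) -> np.ndarray:
        return self.c * 2.0 ** self.exponents

    def __len__(self) -> int:
        return len(self.exponents)

    def sigma_at(self, level: float) -> float:
        """Map a (fractional) level index to sigma by exponential interpolation.

        The exponent is linear in the level index, so ratios between
        fractional levels remain meaningful.
        """
        k = self.k_min + self.k_step * float(level)
        return self.c * 2.0 ** k


@dataclass
class ScaleSpace:
    """Stack of Gaussian-smoothed versions of one image."""

    grid: ScaleGrid
    levels: np.ndarray  # shape (n_levels, H, W)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.grid):
            raise ValueError("level count does not match grid length")


@dataclass(frozen=True)
class ScaleEstimate:
    """Result of the global scale estimation.

    Attributes
    ----------
    s_tilde : float
        Fractional dominant level index in the scale grid.
    s : float
        Dominant spatial scale in sigma units (pixels).
    u : float
        Uncertainty: standard deviation of the fitted Gaussian, in levels.
    valid : bool
        True when the fit converged and ``u / n_levels`` is at most the
        configured threshold.
    """

    s_tilde: float
    s: float
    u: float
    valid: bool

    @staticmethod
    def invalid() -> "ScaleEstimate":
        return ScaleEstimate(s_tilde=np.nan, s=np.nan, u=np.inf, valid=False)


def build_scale_space(image: np.ndarray, grid: ScaleGrid | None = None) -> ScaleSpace:
    """Convolve ``image`` with a Gaussian at every sigma of ``grid``.

    Convolutions are separable with reflective boundary handling; each level
    has the same shape as the input.
    """
    grid = grid or ScaleGrid()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if min(image.shape) < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image too small: need at least {MIN_IMAGE_SIDE} pixels per side"
        )
    levels = np.empty((len(grid),) + image.shape, dtype=np.float64)
    for i, sigma in enumerate(grid.sigmas):
        levels[i] = ndimage.gaussian_filter(image, sigma, mode="reflect")
    return ScaleSpace(grid=grid, levels=levels)


def normalized_laplacian(ss: ScaleSpace) -> np.ndarray:
    """Scale-normalized Laplacian magnitude ``sigma^2 * |Laplacian(L)|`` per level.

    The Laplacian is discretized with the standard 5-point stencil on each
    smoothed level (reflective boundaries).  All values are non-negative.
    """
    out = np.empty_like(ss.levels)
    for i, sigma in enumerate(ss.grid.sigmas):
        lap = ndimage.laplace(ss.levels[i], mode="reflect")
        np.abs(lap, out=lap)
        out[i] = sigma * sigma * lap
    return out


def scale_response(lap_stack: np.ndarray) -> np.ndarray:
    """Sum the normalized-Laplacian magnitude over all pixels, per level."""
    lap_stack = np.asarray(lap_stack)
    if lap_stack.size == 0:
        raise ValueError("empty response stack")
    return lap_stack.reshape(len(lap_stack), -1).sum(axis=1)


def _first_local_maximum(xi: np.ndarray) -> int | None:
    """Index of the first interior local maximum, scanning from small scales.

    A plateau maximum takes its leftmost index; maxima at either endpoint of
    the grid do not qualify as seeds.
    """
    n = len(xi)
    i = 1
    while i < n - 1:
        if xi[i] > xi[i - 1]:
            # walk over a potential plateau
            j = i
            while j + 1 < n and xi[j + 1] == xi[j]:
                j += 1
            if j < n - 1 and xi[j + 1] < xi[j]:
                return i
            i = j + 1
        else:
            i += 1
    return None


def _gaussian(x: np.ndarray, a: float, mu: float, sd: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd * sd))


def estimate_global_scale(
    xi: np.ndarray,
    grid: ScaleGrid | None = None,
    offset_fraction: float = 0.10,
    threshold_t: float | None = None,
) -> ScaleEstimate:
    """Estimate the dominant scale from a response profile ``xi``.

    The first local maximum of ``xi`` seeds a three-parameter Gaussian fit
    restricted to levels within ``+/- round(offset_fraction * n)`` of the
    seed.  The fitted mean is the fractional dominant level, the fitted
    standard deviation the uncertainty ``u``.  The estimate is valid when
    ``u / n <= threshold_t`` (default threshold ``20 / n``).
    """
    grid = grid or ScaleGrid()
    xi = np.asarray(xi, dtype=np.float64)
    n = len(grid)
    if len(xi) != n:
        raise ValueError("response length does not match grid length")
    if threshold_t is None:
        threshold_t = 20.0 / n

    seed = _first_local_maximum(xi)
    if seed is None:
        return ScaleEstimate.invalid()

    off = int(round(offset_fraction * n))
    lo, hi = max(0, seed - off), min(n, seed + off + 1)
    idx = np.arange(lo, hi, dtype=np.float64)
    window = xi[lo:hi]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gaussian,
                idx,
                window,
                p0=(xi[seed], float(seed), 2.0),
                maxfev=10000,
            )
    except (RuntimeError, ValueError):
        return ScaleEstimate.invalid()

    s_tilde = float(popt[1])
    u = abs(float(popt[2]))
    if not np.isfinite(s_tilde) or not np.isfinite(u):
        return ScaleEstimate.invalid()
    valid = (u / n) <= threshold_t
    s = grid.sigma_at(s_tilde)
    if not valid or s <= 0 or not np.isfinite(s):
        return ScaleEstimate(s_tilde=s_tilde, s=s, u=u, valid=False)
    return ScaleEstimate(s_tilde=s_tilde, s=s, u=u, valid=True)


def estimate_scale(image: np.ndarray, grid: ScaleGrid | None = None, **kwargs) -> ScaleEstimate:
    """Convenience pipeline: scale-space -> normalized Laplacian -> estimate."""
    grid = grid or ScaleGrid()
    ss = build_scale_space(image, grid)
    xi = scale_response(normalized_laplacian(ss))
    return estimate_global_scale(xi, grid, **kwargs)
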