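"""Global image orientation from multi-scale second-moment matrices.

The second-moment matrix (structure tensor) at a pixel is the
Gaussian-integrated outer product of scale-space gradients.  Its major
eigen-axis points along the dominant local gradient; the local orientation
is the angle between that axis and the vertical image axis, taken modulo
pi because the axis is unsigned.  Computing the tensors at the estimated
global scale of the image makes the orientation estimate robust to image
scaling.  The global orientation is the mean of a Gaussian fitted to the
histogram of local orientations after trimming bins far from the mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy import ndimage
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "OrientationField",
    "OrientationEstimate",
    "smm_orientation_field",
    "estimate_global_orientation",
    "estimate_orientation",
]


@dataclass
class OrientationField:
    """Local orientations (radians in [0, pi)) sampled on a pixel grid.

    ``angles`` is masked with NaN where the structure tensor is degenerate
    (no gradient signal); those pixels are excluded from the distribution.
    """

    angles: np.ndarray
    local_scale: float
    integration_scale: float

    def defined(self) -> np.ndarray:
        """The defined orientations as a flat array."""
        a = self.angles
        return a[np.isfinite(a)]


@dataclass(frozen=True)
class OrientationEstimate:
    """Global orientation in radians, wrapped to [0, pi)."""

    o: float
    fit_std: float


def smm_orientation_field(
    image: np.ndarray,
    local_scale: float,
    stride: int = 1,
    degenerate_rel_tol: float = 1e-12,
) -> OrientationField:
    """Local orientation of the multi-scale second-moment matrix per pixel.

    Gradients are computed on the scale-space representation at
    ``local_scale`` (Gaussian-derivative filters); the tensor components are
    integrated with a Gaussian at twice the local scale.  The orientation is
    the angle of the major eigenvector measured from the vertical image
    axis, modulo pi.  Pixels whose largest eigenvalue is at most
    ``degenerate_rel_tol`` times the image variance are marked undefined.
    """
    if local_scale <= 0:
        raise ValueError("local_scale must be positive")
    image = np.asarray(image, dtype=np.float64)
    sigma = float(local_scale)
    # axis 0 is y (down), axis 1 is x (right)
    gx = ndimage.gaussian_filter(image, sigma, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(image, sigma, order=(1, 0), mode="reflect")
    integration = 2.0 * sigma
    jxx = ndimage.gaussian_filter(gx * gx, integration, mode="reflect")
    jxy = ndimage.gaussian_filter(gx * gy, integration, mode="reflect")
    jyy = ndimage.gaussian_filter(gy * gy, integration, mode="reflect")

    if stride > 1:
        jxx = jxx[::stride, ::stride]
        jxy = jxy[::stride, ::stride]
        jyy = jyy[::stride, ::stride]

    # Eigen-decomposition of [[jxx, jxy], [jxy, jyy]] in closed form.  The
    # major eigenvector angle from the x-axis is 0.5*atan2(2*jxy, jxx-jyy);
    # the angle from the vertical axis is pi/2 minus that.
    theta_x = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    angles = np.mod(np.pi / 2.0 - theta_x, np.pi)

    tr = jxx + jyy
    disc = np.sqrt(np.maximum((jxx - jyy) ** 2 + 4.0 * jxy ** 2, 0.0))
    lam_max = 0.5 * (tr + disc)
    tol = degenerate_rel_tol * max(float(image.var()), np.finfo(float).tiny)
    angles[lam_max <= tol] = np.nan

    return OrientationField(
        angles=angles, local_scale=sigma, integration_scale=integration
    )


def _gaussian(x: np.ndarray, a: float, mu: float, sd: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd * sd))


def estimate_global_orientation(
    field: OrientationField,
    trim_deg: float = 15.0,
    bin_width_deg: float = 1.0,
) -> OrientationEstimate:
    """Fit a Gaussian to the local-orientation histogram; return its mean.

    The histogram (default 1-degree bins over [0, 180)) is circularly rolled
    so that its mode sits at 90 degrees, bins farther than ``trim_deg`` from
    the mode are discarded, and a three-parameter Gaussian is fitted by
    least squares.  The fitted mean, rolled back and wrapped to [0, pi), is
    the global orientation.
    """
    angles = field.defined()
    if angles.size == 0:
        raise ValueError("no orientation signal: every local orientation undefined")

    deg = np.degrees(angles) % 180.0
    nbins = int(round(180.0 / bin_width_deg))
    hist, edges = np.histogram(deg, bins=nbins, range=(0.0, 180.0))
    centers = 0.5 * (edges[:-1] + edges[1:])

    mode_idx = int(np.argmax(hist))
    # roll the mode to the center bin to avoid wrap-around inside the window
    center_idx = nbins // 2
    shift = center_idx - mode_idx
    rolled = np.roll(hist, shift)

    keep = int(round(trim_deg / bin_width_deg))
    lo, hi = center_idx - keep, center_idx + keep + 1
    x = centers[lo:hi]
    y = rolled[lo:hi].astype(np.float64)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gaussian,
                x,
                y,
                p0=(float(y.max()), centers[center_idx], 5.0),
                maxfev=10000,
            )
        mu, sd = float(popt[1]), abs(float(popt[2]))
    except (RuntimeError, ValueError):
        # fall back to the mode when the fit does not converge
        mu, sd = centers[center_idx], np.inf

    o_deg = (mu - shift * bin_width_deg) % 180.0
    return OrientationEstimate(o=np.radians(o_deg), fit_std=np.radians(sd))


def estimate_orientation(
    image: np.ndarray,
    local_scale: float,
    stride: int = 1,
    trim_deg: float = 15.0,
    bin_width_deg: float = 1.0,
) -> OrientationEstimate:
    """Convenience pipeline: orientation field -> global estimate."""
    field = smm_orientation_field(image, local_scale, stride=stride)
    return estimate_global_orientation(field, trim_deg=trim_deg, bin_width_deg=bin_width_deg)
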