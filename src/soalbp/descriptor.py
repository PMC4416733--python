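"""Multi-resolution meta-descriptors and their distance.

One image yields several adapted LBP histograms: one per base radius
(default {1.5, 3, 4.5}) and, for evaluation images, per candidate texture
class (features adapted against a wrong class's base scale use effectively
random radii and are uninformative, so they only ever get compared against
features of the same reference class).  The set of histograms plus the
scale and orientation estimates forms the meta-descriptor.

Comparing two descriptors first selects, per class, the subset of base
radii whose adapted radii are jointly usable: a pair is dropped when
either radius leaves the discriminative interval [1, 5.44] or the two
radii differ by more than a factor of 3.  The surviving histograms are
concatenated, renormalized, and compared by histogram intersection; the
descriptor distance is the minimum over classes, or infinity when no class
retains a comparable pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .base_scales import TrainedBaseScales, adapted_radius
from .lbp import (
    PatternHistogram,
    adaptive_threshold,
    extract_soa_lbp,
    filter_image,
    sampling_kernel,
    standard_lbp,
)
from .orientation import OrientationEstimate, estimate_orientation
from .scalespace import ScaleEstimate, ScaleGrid, estimate_scale

__all__ = [
    "DEFAULT_BASE_RADII",
    "RADIUS_BOUNDS",
    "MAX_RADIUS_RATIO",
    "MetaDescriptor",
    "build_descriptor",
    "valid_subsets",
    "descriptor_distance",
]

#: Default base radii of the multi-resolution representation: the default
#: radius 3 augmented in equal steps within the most discriminative interval.
DEFAULT_BASE_RADII = (1.5, 3.0, 4.5)

#: Interval of discriminative LBP radii; outside it patterns lose power.
RADIUS_BOUNDS = (1.0, 5.44)

#: Largest usable ratio between two adapted radii of a comparable pair.
MAX_RADIUS_RATIO = 3.0


@dataclass
class MetaDescriptor:
    """All adapted LBP features of one image plus estimation context.

    ``features`` maps ``(class label, base radius)`` to a normalized
    histogram.  Training descriptors hold exactly their own class;
    evaluation descriptors hold every trained class.  When scale estimation
    failed, ``fallback`` is set and the histograms are plain fixed-radius
    LBP at the base radii.
    """

    features: dict
    scale: ScaleEstimate
    orientation: OrientationEstimate | None
    fallback: bool = False
    base_radii: tuple = DEFAULT_BASE_RADII
    label: Hashable | None = None
    image_id: str | None = None

    def classes(self) -> list:
        return sorted({l for (l, _) in self.features}, key=repr)

    def effective_radius(self, label: Hashable, rho: float, base: TrainedBaseScales) -> float:
        """Adapted radius used for (label, rho); the fixed rho under fallback."""
        if self.fallback:
            return float(rho)
        return adapted_radius(self.scale.s, label, rho, base)


def build_descriptor(
    image: np.ndarray,
    base: TrainedBaseScales,
    mode: str = "evaluation",
    own_class: Hashable | None = None,
    base_radii: Sequence[float] = DEFAULT_BASE_RADII,
    n: int = 8,
    grid: ScaleGrid | None = None,
    orientation_stride: int = 1,
    label: Hashable | None = None,
    image_id: str | None = None,
    delta_o_deg: float = 20.0,
    step_deg: float = 5.0,
) -> MetaDescriptor:
    """Estimate scale and orientation once, then extract all adapted features.

    ``mode='training'`` computes features only against ``own_class``'s base
    scale; ``mode='evaluation'`` against every trained class.  When the
    scale estimate is invalid the descriptor falls back to fixed-radius
    standard LBP at the base radii, shared across classes.
    """
    if mode not in ("training", "evaluation"):
        raise ValueError("mode must be 'training' or 'evaluation'")
    if mode == "training" and own_class is None:
        raise ValueError("training mode requires own_class")
    image = np.asarray(image, dtype=np.float64)
    grid = grid or ScaleGrid()
    base_radii = tuple(float(r) for r in base_radii)

    scale = estimate_scale(image, grid)
    classes = [own_class] if mode == "training" else base.classes()

    if not scale.valid:
        # scale-adaption unreliable: fixed-radius multi-resolution LBP
        orient = None
        features = {}
        per_rho = {rho: standard_lbp(image, rho, n) for rho in base_radii}
        for l in classes:
            for rho, h in per_rho.items():
                features[(l, rho)] = PatternHistogram(
                    bins=h.bins,
                    class_ref=l,
                    base_radius=rho,
                    adapted_radius=rho,
                    fallback=True,
                )
        return MetaDescriptor(
            features=features,
            scale=scale,
            orientation=None,
            fallback=True,
            base_radii=base_radii,
            label=label if label is not None else own_class,
            image_id=image_id,
        )

    orient = estimate_orientation(image, scale.s, stride=orientation_stride)

    # one filtered image (and threshold) per unique adapted radius
    cache: dict[float, tuple[np.ndarray, float]] = {}

    def filtered_for(lam: float) -> tuple[np.ndarray, float]:
        key = round(lam, 12)
        if key not in cache:
            fi = filter_image(image, sampling_kernel(lam, n))
            cache[key] = (fi, adaptive_threshold(fi))
        return cache[key]

    features = {}
    for l in classes:
        for rho in base_radii:
            lam = adapted_radius(scale.s, l, rho, base)
            fi, thr = filtered_for(lam)
            features[(l, rho)] = extract_soa_lbp(
                image,
                l,
                scale,
                orient.o,
                rho,
                base,
                n=n,
                delta_o_deg=delta_o_deg,
                step_deg=step_deg,
                threshold=thr,
                filtered=fi,
            )
    return MetaDescriptor(
        features=features,
        scale=scale,
        orientation=orient,
        fallback=False,
        base_radii=base_radii,
        label=label if label is not None else own_class,
        image_id=image_id,
    )


def valid_subsets(
    r1_by_rho: dict,
    r2_by_rho: dict,
    bounds: tuple = RADIUS_BOUNDS,
    max_ratio: float = MAX_RADIUS_RATIO,
) -> list:
    """Base radii whose adapted-radius pair is jointly usable.

    A pair ``(r1, r2)`` survives iff ``min >= bounds[0]``,
    ``max <= bounds[1]`` and ``max/min <= max_ratio``.  The empty result is
    legal and means the two feature sets are incomparable for this class.
    """
    lo, hi = bounds
    keep = []
    for rho in r1_by_rho:
        r1, r2 = r1_by_rho[rho], r2_by_rho[rho]
        mn, mx = min(r1, r2), max(r1, r2)
        if mn < lo or mx > hi or mx / mn > max_ratio:
            continue
        keep.append(rho)
    return keep


def _class_distance(
    m1: MetaDescriptor,
    m2: MetaDescriptor,
    label: Hashable,
    base: TrainedBaseScales,
) -> float:
    rhos = [r for (l, r) in m1.features if l == label and (label, r) in m2.features]
    if not rhos:
        return np.inf
    r1 = {rho: m1.effective_radius(label, rho, base) for rho in rhos}
    r2 = {rho: m2.effective_radius(label, rho, base) for rho in rhos}
    surviving = valid_subsets(r1, r2)
    if not surviving:
        return np.inf
    h1 = np.concatenate([m1.features[(label, rho)].bins for rho in surviving])
    h2 = np.concatenate([m2.features[(label, rho)].bins for rho in surviving])
    # renormalize so the concatenation is again a distribution
    h1 = h1 / h1.sum()
    h2 = h2 / h2.sum()
    return float(1.0 - np.minimum(h1, h2).sum())


def descriptor_distance(
    m1: MetaDescriptor,
    m2: MetaDescriptor,
    base: TrainedBaseScales,
) -> float:
    """Minimum histogram-intersection distance over comparable classes.

    Features adapted against different classes are incomparable (distance
    infinity), so only histograms sharing a reference class contribute;
    returns infinity when every class yields an empty valid subset.
    """
    common = set(m1.classes()) & set(m2.classes())
    if not common:
        return np.inf
    return min(_class_distance(m1, m2, l, base) for l in common)
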