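"""Per-class trained base scales and intrinsic-scale-adapted LBP radii.

The visualized scale of a texture confounds the camera scale with the
texture's intrinsic scale (the spatial extent of its dominant structures).
Taking the quotient of an image's estimated scale and a per-class
reference scale cancels the intrinsic scale when the image belongs to that
class, so LBP radii adapted as ``lambda = rho * s / s_bar_l`` track the
camera scale only.  The reference ("trained base scale") of a class is the
median estimated scale over its training images.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Hashable, Iterable, Mapping

import numpy as np

__all__ = ["TrainedBaseScales", "train_base_scales", "adapted_radius"]


@dataclass(frozen=True)
class TrainedBaseScales:
    """Mapping texture class -> trained base scale (sigma units, pixels)."""

    scales: Mapping[Hashable, float]

    def __post_init__(self) -> None:
        for label, s in self.scales.items():
            if not (s > 0):
                raise ValueError(f"non-positive base scale for class {label!r}")

    def __getitem__(self, label: Hashable) -> float:
        try:
            return self.scales[label]
        except KeyError:
            raise KeyError(f"unknown texture class {label!r}") from None

    def __contains__(self, label: Hashable) -> bool:
        return label in self.scales

    def classes(self) -> list:
        return list(self.scales)


def train_base_scales(estimates: Mapping[Hashable, Iterable]) -> TrainedBaseScales:
    """Median valid estimated scale per class.

    ``estimates`` maps each class label to its scale estimates (either
    ``ScaleEstimate`` objects or plain positive floats).  Estimates flagged
    invalid are excluded; a class with no valid estimate raises an error
    naming it.
    """
    table = {}
    for label, ests in estimates.items():
        values = []
        for e in ests:
            if hasattr(e, "valid"):
                if e.valid:
                    values.append(float(e.s))
            else:
                values.append(float(e))
        if not values:
            raise ValueError(f"no valid scale estimate for class {label!r}")
        table[label] = float(median(values))
    return TrainedBaseScales(scales=table)


def adapted_radius(s: float, label: Hashable, rho: float, base: TrainedBaseScales) -> float:
    """Intrinsic-scale-adapted LBP radius ``lambda = rho * s / s_bar_l``.

    Linear in the estimated scale ``s``, which is the property that makes
    the adapted representation scale-invariant.
    """
    if not (s > 0):
        raise ValueError("estimated scale must be positive")
    return float(rho) * float(s) / base[label]
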