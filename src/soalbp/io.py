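"""Image reading and the JSON-lines descriptor store.

Images are loaded as 2-D float grids in the 8-bit range [0, 255]; color
inputs are reduced by channel mean and 16-bit inputs rescaled.  Descriptor
stores hold the trained base scales plus any number of meta-descriptor
records in a versioned, human-inspectable JSON-lines file: the first line
is a header with the version and base scales, every further line one
descriptor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .base_scales import TrainedBaseScales
from .descriptor import MetaDescriptor
from .lbp import PatternHistogram
from .orientation import OrientationEstimate
from .scalespace import ScaleEstimate

__all__ = ["STORE_VERSION", "DescriptorStore", "read_image", "write_image", "save_store", "load_store"]

STORE_VERSION = "soalbp-store/1"


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a 2-D float array in [0, 255].

    Multi-channel images are converted by the mean over channels; 16-bit
    data is rescaled to the 8-bit range.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise OSError(f"unsupported image layout in {path}: ndim={arr.ndim}")
    if arr.max() > 255.0:  # 16-bit source
        arr = arr * (255.0 / 65535.0)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 255] as an 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0, 255)
    Image.fromarray(np.round(arr).astype(np.uint8)).save(Path(path))


@dataclass
class DescriptorStore:
    """Trained base scales plus labeled meta-descriptor records."""

    base_scales: TrainedBaseScales
    descriptors: list = field(default_factory=list)
    version: str = STORE_VERSION


def _num(x: float) -> float | str:
    if math.isnan(x):
        return "nan"
    if math.isinf(x):
        return "inf"
    return float(x)


def _unnum(x) -> float:
    if x == "nan":
        return math.nan
    if x == "inf":
        return math.inf
    return float(x)


def _descriptor_record(d: MetaDescriptor) -> dict:
    # class labels are stringified on disk; load a store's descriptors together
    # with its own base-scales header so keys stay consistent
    feats = [
        {
            "class": str(f.class_ref),
            "rho": f.base_radius,
            "lambda": f.adapted_radius,
            "bins": f.bins.tolist(),
        }
        for f in d.features.values()
    ]
    return {
        "image_id": d.image_id,
        "label": None if d.label is None else str(d.label),
        "fallback": d.fallback,
        "base_radii": list(d.base_radii),
        "scale": {
            "s_tilde": _num(d.scale.s_tilde),
            "s": _num(d.scale.s),
            "u": _num(d.scale.u),
            "valid": d.scale.valid,
        },
        "orientation": None
        if d.orientation is None
        else {"o": d.orientation.o, "fit_std": _num(d.orientation.fit_std)},
        "features": feats,
    }


def _descriptor_from_record(rec: dict) -> MetaDescriptor:
    features = {}
    for f in rec["features"]:
        bins = np.asarray(f["bins"], dtype=np.float64)
        if abs(bins.sum() - 1.0) > 1e-6:
            raise ValueError("corrupt store: histogram does not sum to 1")
        features[(f["class"], f["rho"])] = PatternHistogram(
            bins=bins,
            class_ref=f["class"],
            base_radius=f["rho"],
            adapted_radius=f["lambda"],
            fallback=rec["fallback"],
        )
    sc = rec["scale"]
    orient = rec["orientation"]
    return MetaDescriptor(
        features=features,
        scale=ScaleEstimate(
            s_tilde=_unnum(sc["s_tilde"]), s=_unnum(sc["s"]), u=_unnum(sc["u"]), valid=sc["valid"]
        ),
        orientation=None
        if orient is None
        else OrientationEstimate(o=orient["o"], fit_std=_unnum(orient["fit_std"])),
        fallback=rec["fallback"],
        base_radii=tuple(rec["base_radii"]),
        label=rec["label"],
        image_id=rec["image_id"],
    )


def save_store(store: DescriptorStore, path: str | Path) -> None:
    """Write the store as JSON lines (header line + one line per descriptor)."""
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "version": store.version,
            "base_scales": {str(k): v for k, v in store.base_scales.scales.items()},
            "class_order": [str(k) for k in store.base_scales.scales],
        }
        fh.write(json.dumps(header) + "\n")
        for d in store.descriptors:
            fh.write(json.dumps(_descriptor_record(d)) + "\n")


def load_store(path: str | Path) -> DescriptorStore:
    """Load a store, validating version and histogram normalization."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty descriptor store: {path}")
    try:
        header = json.loads(lines[0])
        if header.get("version") != STORE_VERSION:
            raise ValueError(
                f"store version mismatch: got {header.get('version')!r}, "
                f"expected {STORE_VERSION!r}"
            )
        base = TrainedBaseScales(scales=dict(header["base_scales"]))
        descriptors = [_descriptor_from_record(json.loads(ln)) for ln in lines[1:]]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt descriptor store {path}: {exc}") from exc
    return DescriptorStore(base_scales=base, descriptors=descriptors, version=STORE_VERSION)
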