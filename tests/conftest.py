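import numpy as np
import pytest

from soalbp import (
    CVConfig,
    TextureSpec,
    TrainedBaseScales,
    build_descriptor,
    distance_matrix,
    estimate_scale,
    make_texture,
    train_base_scales,
    transform,
)

#: Texture kinds of the three-class synthetic fixture set.
FIXTURE_KINDS = {"A": "blobs", "B": "oriented-noise", "C": "grating"}
FIXTURE_SCALE = 4.0


def _fixture_orientation(seed: int) -> float:
    """Per-texture random dominant orientation, decoupled from the field seed."""
    return float(np.random.default_rng(seed ^ 0x5DEECE).uniform(0, np.pi))


def fixture_texture(cls: str, seed: int, size: int = 224) -> np.ndarray:
    return make_texture(
        TextureSpec(
            kind=FIXTURE_KINDS[cls],
            dominant_scale=FIXTURE_SCALE,
            dominant_orientation=_fixture_orientation(seed),
            size=size,
            seed=seed,
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def toy_base():
    return TrainedBaseScales({"A": 3.0, "B": 4.0, "C": 5.0})


@pytest.fixture(scope="session")
def three_class_set():
    """Equal-scale three-class descriptor set with a precomputed distance matrix.

    Five training and three evaluation textures per class, all at the base
    camera scale, designed so that classes separate cleanly.
    """
    train_imgs, train_labels, eval_imgs, eval_labels = [], [], [], []
    seed = 100
    for cls in FIXTURE_KINDS:
        for _ in range(5):
            train_imgs.append(transform(fixture_texture(cls, seed), 1.0, 0.0))
            train_labels.append(cls)
            seed += 1
        for _ in range(3):
            eval_imgs.append(transform(fixture_texture(cls, seed), 1.0, 0.0))
            eval_labels.append(cls)
            seed += 1

    per_class = {}
    for img, l in zip(train_imgs, train_labels):
        per_class.setdefault(l, []).append(estimate_scale(img))
    base = train_base_scales(per_class)
    train_desc = [
        build_descriptor(img, base, mode="training", own_class=l)
        for img, l in zip(train_imgs, train_labels)
    ]
    eval_desc = [build_descriptor(img, base, mode="evaluation") for img in eval_imgs]
    dists = distance_matrix(eval_desc, train_desc, base)
    return {
        "base": base,
        "train_desc": train_desc,
        "train_labels": train_labels,
        "eval_desc": eval_desc,
        "eval_labels": eval_labels,
        "dists": dists,
    }
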