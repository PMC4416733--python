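"""Meta-descriptors and their histogram-intersection distance.

Trains base scales from a few labeled textures, builds training and
evaluation descriptors, and compares same-class against cross-class
distances.  Also demonstrates the valid-subset selection that limits
comparisons to jointly usable radii.
"""

import numpy as np

from soalbp import (
    TextureSpec,
    build_descriptor,
    descriptor_distance,
    estimate_scale,
    make_texture,
    train_base_scales,
    transform,
    valid_subsets,
)

kinds = {"blobs": "blobs", "streaks": "oriented-noise"}
train, ests = {}, {}
seed = 0
for name, kind in kinds.items():
    imgs = [make_texture(TextureSpec(kind=kind, dominant_scale=4.0, seed=seed + i))
            for i in range(4)]
    seed += 4
    train[name] = imgs
    ests[name] = [estimate_scale(im) for im in imgs]
base = train_base_scales(ests)
print("trained base scales:", {k: round(v, 2) for k, v in base.scales.items()})

train_desc = {
    name: build_descriptor(imgs[0], base, mode="training", own_class=name)
    for name, imgs in train.items()
}
query_img = make_texture(TextureSpec(kind="blobs", dominant_scale=4.0, seed=99))
query = build_descriptor(query_img, base, mode="evaluation")

for name, td in train_desc.items():
    d = descriptor_distance(query, td, base)
    print(f"distance of a fresh blobs texture to class {name!r}: {d:.3f}")
print("the smaller distance identifies the matching class")

# the subset selection drops radii pairs that scaling made incomparable
r1 = {rho: rho for rho in (1.5, 3.0, 4.5)}
r2 = {rho: 2.5 * rho for rho in (1.5, 3.0, 4.5)}
print(f"valid base radii at a 2.5x scale difference: {valid_subsets(r1, r2)}")
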