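"""kNN classification over meta-descriptor distances and the
scale-constrained cross-validation protocol.

Training descriptors are always extracted at one fixed camera scale while
evaluation descriptors come from a probe scale, so accuracy as a function
of the probe scale measures scale invariance.  Each cross-validation
iteration draws a stratified 75% subset of the training images and a 25%
subset of the evaluation images, classifies with k-nearest neighbors for
every k up to the per-class training count (capped at 20), and the
reported accuracy is the mean over all k values and iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .base_scales import TrainedBaseScales
from .descriptor import MetaDescriptor, descriptor_distance

__all__ = [
    "UNCLASSIFIABLE",
    "CVConfig",
    "distance_matrix",
    "knn_from_distances",
    "knn_classify",
    "scale_constrained_cv",
]

#: Label returned when every training distance is infinite; counted as an
#: error in accuracy.
UNCLASSIFIABLE = "__unclassifiable__"


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters."""

    train_fraction: float = 0.75
    eval_fraction: float = 0.25
    iterations: int = 100
    k_max: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction <= 1 and 0 < self.eval_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


def distance_matrix(
    queries: Sequence[MetaDescriptor],
    training: Sequence[MetaDescriptor],
    base: TrainedBaseScales,
) -> np.ndarray:
    """Dense matrix of descriptor distances, queries by rows."""
    out = np.empty((len(queries), len(training)))
    for i, q in enumerate(queries):
        for j, t in enumerate(training):
            out[i, j] = descriptor_distance(q, t, base)
    return out


def knn_from_distances(
    dists: np.ndarray,
    labels: Sequence[Hashable],
    k: int,
) -> Hashable:
    """Majority vote over the k nearest training items.

    Infinite distances rank last; ties on distance are broken by training
    order (stable sort), ties on vote count by the smallest mean distance
    among the tied classes.  When every distance is infinite the query is
    unclassifiable.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    dists = np.asarray(dists, dtype=np.float64)
    if len(dists) == 0:
        raise ValueError("empty training set")
    if np.all(np.isinf(dists)):
        return UNCLASSIFIABLE
    order = np.argsort(dists, kind="stable")[: min(k, len(dists))]
    votes: dict = {}
    sums: dict = {}
    for idx in order:
        if np.isinf(dists[idx]):
            continue
        l = labels[idx]
        votes[l] = votes.get(l, 0) + 1
        sums[l] = sums.get(l, 0.0) + dists[idx]
    best = max(votes.values())
    tied = [l for l, v in votes.items() if v == best]
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda l: (sums[l] / votes[l], repr(l)))


def knn_classify(
    query: MetaDescriptor,
    training: Sequence[MetaDescriptor],
    labels: Sequence[Hashable],
    base: TrainedBaseScales,
    k: int = 1,
) -> Hashable:
    """Classify one descriptor against labeled training descriptors."""
    dists = np.array([descriptor_distance(query, t, base) for t in training])
    return knn_from_distances(dists, labels, k)


def _stratified_sample(
    labels: Sequence[Hashable], fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a per-class random subset covering every class at least once."""
    labels = np.asarray(labels, dtype=object)
    picked = []
    for l in sorted(set(labels.tolist()), key=repr):
        idx = np.flatnonzero(labels == l)
        m = max(1, int(round(fraction * len(idx))))
        picked.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(picked))


def scale_constrained_cv(
    eval_train_dists: np.ndarray,
    train_labels: Sequence[Hashable],
    eval_labels: Sequence[Hashable],
    cfg: CVConfig,
) -> tuple[float, float, np.ndarray]:
    """Mean accuracy of the iterated, scale-constrained protocol.

    ``eval_train_dists`` is the precomputed distance matrix between all
    evaluation descriptors (rows) and all training descriptors (columns).
    Returns ``(mean, std, per_iteration)`` where the mean is taken over all
    k values and iterations and the std is across iterations (the error-bar
    quantity).  Identical seeds yield identical subsets and accuracies.
    """
    train_labels = np.asarray(train_labels, dtype=object)
    eval_labels = np.asarray(eval_labels, dtype=object)
    rng = np.random.default_rng(cfg.seed)
    per_iter = np.empty(cfg.iterations)
    for it in range(cfg.iterations):
        tr = _stratified_sample(train_labels, cfg.train_fraction, rng)
        ev = _stratified_sample(eval_labels, cfg.eval_fraction, rng)
        sub = eval_train_dists[np.ix_(ev, tr)]
        sub_train_labels = train_labels[tr]
        counts = [np.sum(sub_train_labels == l) for l in set(sub_train_labels.tolist())]
        k_hi = min(cfg.k_max, int(min(counts)))
        accs = []
        for k in range(1, k_hi + 1):
            pred = [knn_from_distances(sub[i], sub_train_labels, k) for i in range(len(ev))]
            accs.append(float(np.mean([p == t for p, t in zip(pred, eval_labels[ev])])))
        per_iter[it] = float(np.mean(accs))
    return float(per_iter.mean()), float(per_iter.std()), per_iter
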