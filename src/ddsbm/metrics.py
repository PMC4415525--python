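"""Partition-agreement metrics and perturbation operators.

ARI, homogeneity and completeness compare a discovered typing against a
reference (e.g. anatomist labels); all three equal 1.0 on identical
partitions.  Homogeneity penalizes found types that mix true types;
completeness penalizes true types split across found types — so
splitting a type leaves homogeneity at 1.0 while lowering completeness,
and merging two types does the reverse.  The perturbation operators
(distribute / merge / split) make that asymmetry directly testable.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    completeness_score,
    homogeneity_score,
)

from .core import Assignment, EntityGeometry


def _labels(a) -> np.ndarray:
    return a.labels if isinstance(a, Assignment) else np.asarray(a)


def _check_lengths(a, b):
    la, lb = _labels(a), _labels(b)
    if la.size != lb.size:
        raise ValueError(f"label vectors differ in length: {la.size} vs {lb.size}")
    return la, lb


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand index; 1.0 iff the partitions are identical."""
    la, lb = _check_lengths(a, b)
    return float(adjusted_rand_score(la, lb))


def homogeneity(truth, found) -> float:
    """1 - H(truth | found) / H(truth): do found types contain one true type?"""
    lt, lf = _check_lengths(truth, found)
    return float(homogeneity_score(lt, lf))


def completeness(truth, found) -> float:
    """1 - H(found | truth) / H(found): does each true type stay together?"""
    lt, lf = _check_lengths(truth, found)
    return float(completeness_score(lt, lf))


def perturb_distribute(a, type_id: int, rng=None) -> Assignment:
    """Dissolve one type, reassigning members uniformly among the others."""
    labels = _labels(a).copy()
    rng = np.random.default_rng(rng)
    types = np.unique(labels)
    if types.size < 2:
        raise ValueError("cannot distribute the only type")
    if type_id not in types:
        raise ValueError(f"type {type_id} not present")
    others = types[types != type_id]
    members = np.flatnonzero(labels == type_id)
    labels[members] = rng.choice(others, size=members.size)
    return Assignment(labels).relabeled()


def perturb_merge(a, type_a: int, type_b: int) -> Assignment:
    """Merge type_a into type_b (K decreases by one)."""
    if type_a == type_b:
        raise ValueError("merge requires two distinct types")
    labels = _labels(a).copy()
    types = np.unique(labels)
    if type_a not in types or type_b not in types:
        raise ValueError("both types must be present")
    labels[labels == type_a] = type_b
    return Assignment(labels).relabeled()


def perturb_split(a, type_id: int, rng=None) -> Assignment:
    """Randomly bisect one type into two new types (K increases by one)."""
    labels = _labels(a).copy()
    rng = np.random.default_rng(rng)
    members = np.flatnonzero(labels == type_id)
    if members.size < 2:
        raise ValueError("cannot split a singleton type")
    half = rng.permutation(members)[: members.size // 2]
    labels[half] = labels.max() + 1
    return Assignment(labels).relabeled()


def spatial_extent(assignment, geometry: EntityGeometry, dims=(0, 1)) -> np.ndarray:
    """Per-type RMS deviation of member positions from the type centroid.

    ``dims`` selects the lateral plane (first two coordinates by
    default; for 1-D geometries the single coordinate is used).
    """
    labels = _labels(assignment)
    pos = geometry.positions
    dims = tuple(d for d in dims if d < pos.shape[1])
    k = labels.max() + 1
    out = np.zeros(k)
    for m in range(k):
        p = pos[np.ix_(labels == m, dims)]
        if p.shape[0] == 0:
            continue
        out[m] = np.sqrt(((p - p.mean(axis=0)) ** 2).sum(axis=1).mean())
    return out


__all__ = [
    "adjusted_rand_index",
    "homogeneity",
    "completeness",
    "perturb_distribute",
    "perturb_merge",
    "perturb_split",
    "spatial_extent",
]
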