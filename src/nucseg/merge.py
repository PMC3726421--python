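"""Cross-scale merging of concurrent candidate regions.

Nine scales times two marker types yield up to 18 segmentations of each
nucleus; near-identical candidates from neighboring scales, nested
sub-structure segmentations and over-segmentations must be reduced to one
region per nucleus. Pairwise conflict is measured with the containment
overlap

    OV(Xi, Xj) = |Xi ∩ Xj| / min(|Xi|, |Xj|)

and two candidates are *adjacent* (in conflict) when OV exceeds a threshold
(default 0.2 — small overlaps of genuinely touching nuclei are tolerated).
Conflicts are resolved greedily: accept the candidate with the highest
fitness (its solidity), reject everything adjacent to it, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .features import EllipseRegion, rasterize_ellipse

__all__ = [
    "DEFAULT_OVERLAP_THRESHOLD",
    "CandidatePool",
    "overlap_measure",
    "build_adjacency",
    "resolve_overlaps",
]

DEFAULT_OVERLAP_THRESHOLD = 0.2

_MARKER_ORDER = {"frst": 0, "minima": 1}


def overlap_measure(xi, xj) -> float:
    """Containment overlap |Xi ∩ Xj| / min(|Xi|, |Xj|) of two pixel sets.

    Pixel sets are 1-D arrays of flattened pixel indices (each with unique
    entries). 1.0 when one region contains the other, 0.0 when disjoint.
    """
    xi = np.asarray(xi)
    xj = np.asarray(xj)
    if xi.size == 0 or xj.size == 0:
        raise ValueError("overlap measure is undefined for an empty region")
    inter = np.intersect1d(xi, xj, assume_unique=True).size
    return inter / min(xi.size, xj.size)


def _flat_pixels(ellipse: EllipseRegion, shape) -> np.ndarray:
    rows, cols = rasterize_ellipse(ellipse, shape)
    return np.sort(rows.astype(np.int64) * shape[1] + cols)


@dataclass
class CandidatePool:
    """Candidate ellipses from all scales/marker types plus their conflicts.

    Overlaps are computed on the rasterized ellipse interiors (the merging
    stage runs after ellipse standardization).
    """

    candidates: List[EllipseRegion]
    shape: tuple
    pixels: list = field(default_factory=list)
    adjacency: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.pixels:
            self.pixels = [_flat_pixels(e, self.shape) for e in self.candidates]


def build_adjacency(
    pool: CandidatePool, th: float = DEFAULT_OVERLAP_THRESHOLD
) -> np.ndarray:
    """Symmetric boolean adjacency: A[i, j] = 1 iff OV(Xi, Xj) > th (strict).

    A pair at exactly the threshold is "touching", not adjacent, and both
    members may survive the merge.
    """
    k = len(pool.candidates)
    adj = np.zeros((k, k), dtype=bool)
    # bounding circles give a cheap disjointness prefilter
    cx = np.array([e.center_x for e in pool.candidates])
    cy = np.array([e.center_y for e in pool.candidates])
    ra = np.array([e.semi_major for e in pool.candidates])
    for i in range(k):
        if pool.pixels[i].size == 0:
            continue
        near = np.hypot(cx - cx[i], cy - cy[i]) <= ra + ra[i]
        for j in range(i + 1, k):
            if not near[j] or pool.pixels[j].size == 0:
                continue
            if overlap_measure(pool.pixels[i], pool.pixels[j]) > th:
                adj[i, j] = adj[j, i] = True
    pool.adjacency = adj
    return adj


def resolve_overlaps(
    pool: CandidatePool, th: float = DEFAULT_OVERLAP_THRESHOLD
) -> List[EllipseRegion]:
    """Greedy conflict resolution on the candidate pool.

    Repeatedly accept the unresolved candidate with the maximum fitness and
    reject all candidates adjacent to it, until every candidate is accepted
    or rejected. Fitness ties are broken deterministically by larger area,
    then lower scale, then FRST before minima markers, then input order.
    Accepted regions are returned in acceptance order; no accepted pair is
    adjacent.
    """
    if pool.adjacency is None:
        build_adjacency(pool, th)
    k = len(pool.candidates)
    order = sorted(
        range(k),
        key=lambda i: (
            -pool.candidates[i].fitness,
            -pool.candidates[i].area,
            pool.candidates[i].scale,
            _MARKER_ORDER.get(pool.candidates[i].marker_type, 2),
            i,
        ),
    )
    state = np.zeros(k, dtype=np.int8)  # 0 unresolved, 1 accepted, -1 rejected
    accepted: List[EllipseRegion] = []
    for i in order:
        if state[i] != 0:
            continue
        state[i] = 1
        accepted.append(pool.candidates[i])
        state[pool.adjacency[i] & (state == 0)] = -1
    return accepted
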