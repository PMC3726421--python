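"""Dice-based segmentation scoring and mean nuclear area estimation.

A ground-truth nucleus counts as detected (TP) when some automatic region
overlaps it with a Dice coefficient of at least a cutoff (default 0.2 — low
enough to tolerate imperfect contours, high enough that a neighbor merely
touching an unsegmented nucleus does not count). Sensitivity is
TP / (TP + FN); object-level positive predictive value is the fraction of
automatic regions whose best Dice against any ground-truth nucleus reaches
the cutoff. Segmentation quality is summarized by the median Dice over
matched pairs (the Dice distribution is left-skewed, so the median is the
better central-tendency measure).

Mean nuclear area (MNA) — the average area of the accepted ellipses — is a
prognostic morphometric parameter. Automatic MNA is systematically
underestimated (small junk segmentations, under-segmentation of large
nuclei), so a linear regression fitted on paired automatic/manual MNA
values over a training set of images supplies a correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "EvaluationReport",
    "dice_coefficient",
    "match_and_score",
    "mean_nuclear_area",
    "fit_mna_correction",
    "masks_from_label_map",
]


def dice_coefficient(x, y) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|) of two pixel sets (flat indices)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("Dice coefficient is undefined for an empty region")
    inter = np.intersect1d(x, y, assume_unique=True).size
    return 2.0 * inter / (x.size + y.size)


@dataclass(frozen=True)
class EvaluationReport:
    """Detection and segmentation scores for one image."""

    tp: int
    fn: int
    sensitivity: float
    ppv: Optional[float]  # None when there are no automatic regions
    dice_values: Tuple[float, ...]  # best Dice of each matched ground-truth nucleus
    median_dice: Optional[float]  # over matched (TP) nuclei only
    median_dice_all: Optional[float]  # over all ground-truth nuclei, FN as 0


def masks_from_label_map(labels: np.ndarray) -> List[np.ndarray]:
    """Flat pixel-index sets of every nonzero label, ordered by label id."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_vals = flat[order]
    sets = []
    for lab in np.unique(sorted_vals):
        if lab == 0:
            continue
        lo = np.searchsorted(sorted_vals, lab, side="left")
        hi = np.searchsorted(sorted_vals, lab, side="right")
        sets.append(np.sort(order[lo:hi]))
    return sets


def _bbox(pixels: np.ndarray, width: int) -> Tuple[int, int, int, int]:
    rows = pixels // width
    cols = pixels % width
    return rows.min(), rows.max(), cols.min(), cols.max()


def match_and_score(
    gt: Sequence[np.ndarray],
    result: Sequence[np.ndarray],
    shape: Tuple[int, int],
    cutoff: float = 0.2,
) -> EvaluationReport:
    """Score automatic regions against ground-truth nuclei.

    Parameters
    ----------
    gt, result
        Sequences of flat pixel-index sets (sorted, unique) in a common
        image frame of the given ``shape``.
    cutoff
        Dice threshold for a ground-truth nucleus to count as detected.

    Matching is per-ground-truth best Dice without exclusivity: one
    automatic region may be the best match of several ground-truth nuclei.
    """
    if len(gt) == 0:
        raise ValueError("ground truth is empty")
    w = shape[1]
    if len(result) == 0:
        return EvaluationReport(0, len(gt), 0.0, None, (), None, 0.0)

    gt_boxes = [_bbox(g, w) for g in gt]
    res_boxes = [_bbox(r, w) for r in result]

    best_gt = np.zeros(len(gt))
    best_res = np.zeros(len(result))
    for i, g in enumerate(gt):
        gr0, gr1, gc0, gc1 = gt_boxes[i]
        for j, r in enumerate(result):
            rr0, rr1, rc0, rc1 = res_boxes[j]
            if rr0 > gr1 or gr0 > rr1 or rc0 > gc1 or gc0 > rc1:
                continue
            d = dice_coefficient(g, r)
            if d > best_gt[i]:
                best_gt[i] = d
            if d > best_res[j]:
                best_res[j] = d

    matched = best_gt >= cutoff
    tp = int(matched.sum())
    fn = len(gt) - tp
    dice_values = tuple(best_gt[matched])
    median_dice = float(np.median(best_gt[matched])) if tp else None
    all_dice = np.where(matched, best_gt, 0.0)
    return EvaluationReport(
        tp=tp,
        fn=fn,
        sensitivity=tp / len(gt),
        ppv=float(np.mean(best_res >= cutoff)),
        dice_values=dice_values,
        median_dice=median_dice,
        median_dice_all=float(np.median(all_dice)),
    )


def mean_nuclear_area(
    areas: Sequence[float], correction: Optional[Tuple[float, float]] = None
) -> Tuple[float, Optional[float]]:
    """Raw and (optionally) linearly corrected mean nuclear area.

    ``areas`` are the areas of the accepted regions (for ellipses,
    pi*a*b). ``correction`` is a (slope, intercept) pair applied to the raw
    mean; pass ``None`` to skip.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("mean nuclear area requires at least one region")
    raw = float(areas.mean())
    if correction is None:
        return raw, None
    slope, intercept = correction
    return raw, slope * raw + intercept


def fit_mna_correction(
    automatic: Sequence[float], manual: Sequence[float]
) -> Tuple[float, float]:
    """Least-squares (slope, intercept) mapping automatic MNA to manual MNA."""
    x = np.asarray(list(automatic), dtype=float)
    y = np.asarray(list(manual), dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired MNA values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
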