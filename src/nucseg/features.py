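"""Region feature extraction, rule-based rejection and ellipse standardization.

Watershed regions that do not look like nuclei are rejected with a simple
rule-based scheme on four features:

* solidity ``s`` — region area over convex-hull area; nuclei are rarely
  concave, so correct segmentations score close to 1;
* boundary saliency ``l`` — median intensity in a tight band just outside
  the region minus the median just inside; a dark nucleus on brighter
  surround scores strongly positive;
* mass displacement ``d`` — distance between the centroid and the
  inverse-intensity-weighted centroid, normalized by the minor axis of the
  region's moment ellipse; near zero for symmetric intensity content;
* area, bounded per scale by the plausible nucleus size range.

Accepted ranges: s in (0.875, 1), l in (20, 255), d in [0, 0.08],
n^2*pi <= area <= 4*n^2*pi. Survivors are standardized as moment-matched
ellipses so contour coarseness no longer depends on the extraction scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

from .morphology import PreprocessedImage, disk_footprint

__all__ = [
    "RegionFeatures",
    "EllipseRegion",
    "FeatureRanges",
    "DEFAULT_FEATURE_RANGES",
    "compute_region_features",
    "extract_candidates",
    "filter_candidates",
    "fit_ellipse",
    "rasterize_ellipse",
]


@dataclass(frozen=True)
class RegionFeatures:
    """Scalar features of one watershed region."""

    solidity: float
    saliency: Optional[float]  # None when the outer band is empty (border region)
    displacement: float
    area: int

    @property
    def saliency_defined(self) -> bool:
        return self.saliency is not None


@dataclass(frozen=True)
class FeatureRanges:
    """Accepted feature intervals; bounds carry their printed open/closed sense."""

    solidity: tuple = (0.875, 1.0)  # open interval
    saliency: tuple = (20.0, 255.0)  # open interval
    displacement: tuple = (0.0, 0.08)  # closed interval

    def accepts(self, f: RegionFeatures, n: int) -> bool:
        if f.saliency is None:
            return False
        min_area = np.pi * n * n
        max_area = 4.0 * np.pi * n * n
        return (
            self.solidity[0] < f.solidity < self.solidity[1]
            and self.saliency[0] < f.saliency < self.saliency[1]
            and self.displacement[0] <= f.displacement <= self.displacement[1]
            and min_area <= f.area <= max_area
        )


DEFAULT_FEATURE_RANGES = FeatureRanges()

#: half-width of the inner/outer intensity bands for boundary saliency, px
DEFAULT_BAND_WIDTH = 3


def _moment_ellipse(rows: np.ndarray, cols: np.ndarray):
    """Centroid, semi-axes and orientation of the moment-matched ellipse.

    Orientation is the angle of the major axis from the +x (column) axis,
    y pointing down, normalized to [0, pi). Semi-axes follow the solid
    ellipse relation a = 2*sqrt(lambda_max) on the second central moments.
    """
    x = cols.astype(float)
    y = rows.astype(float)
    cx, cy = x.mean(), y.mean()
    mu20 = ((x - cx) ** 2).mean()
    mu02 = ((y - cy) ** 2).mean()
    mu11 = ((x - cx) * (y - cy)).mean()
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam_max = (mu20 + mu02 + common) / 2.0
    lam_min = (mu20 + mu02 - common) / 2.0
    a = 2.0 * np.sqrt(max(lam_max, 0.0))
    b = 2.0 * np.sqrt(max(lam_min, 0.0))
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    return (cx, cy), a, b, theta % np.pi


def compute_region_features(
    region_mask: np.ndarray,
    pre: PreprocessedImage | np.ndarray,
    band_width: int = DEFAULT_BAND_WIDTH,
) -> RegionFeatures:
    """Compute solidity, boundary saliency, mass displacement and area.

    ``region_mask`` is a boolean mask in the full image frame. Saliency is
    ``None`` (region flagged for rejection) when the outer band falls
    entirely outside the frame.
    """
    img = pre.pixels if isinstance(pre, PreprocessedImage) else np.asarray(pre, float)
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("region is empty")
    area = int(mask.sum())

    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    pad = band_width + 1
    pr0, pc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    pr1, pc1 = min(r1 + pad, mask.shape[0]), min(c1 + pad, mask.shape[1])
    crop = mask[pr0:pr1, pc0:pc1]
    img_crop = img[pr0:pr1, pc0:pc1]

    hull = convex_hull_image(crop)
    solidity = area / float(hull.sum())

    fp = disk_footprint(band_width)
    outer = ndi.binary_dilation(crop, structure=fp) & ~crop
    inner = crop & ~ndi.binary_erosion(crop, structure=fp)
    saliency = None
    if outer.any():
        saliency = float(np.median(img_crop[outer]) - np.median(img_crop[inner]))

    (cx, cy), _, b_axis, _ = _moment_ellipse(rows, cols)
    weights = 256.0 - img[rows, cols]
    wsum = weights.sum()
    wx = (cols * weights).sum() / wsum
    wy = (rows * weights).sum() / wsum
    minor_axis = 2.0 * b_axis  # full minor-axis length of the moment ellipse
    if minor_axis <= 0:
        displacement = np.inf
    else:
        displacement = float(np.hypot(wx - cx, wy - cy) / minor_axis)

    return RegionFeatures(float(solidity), saliency, displacement, area)


@dataclass(frozen=True)
class EllipseRegion:
    """Elliptical standardization of an accepted watershed region.

    Coordinates are 0-based pixels, ``x`` = column, ``y`` = row; the
    orientation is the major-axis angle from +x in radians, in [0, pi).
    ``fitness`` is the solidity of the source region and drives the
    cross-scale merging.
    """

    center_x: float
    center_y: float
    semi_major: float
    semi_minor: float
    orientation: float
    scale: int
    marker_type: str
    fitness: float

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if not 0 <= self.orientation < np.pi:
            raise ValueError("orientation must lie in [0, pi)")

    @property
    def area(self) -> float:
        return np.pi * self.semi_major * self.semi_minor


def fit_ellipse(
    region_mask: np.ndarray,
    scale: int = 0,
    marker_type: str = "frst",
    fitness: float = 0.0,
) -> EllipseRegion:
    """Moment-based ellipse with the region's second central moments."""
    mask = np.asarray(region_mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size < 5:
        raise ValueError(f"region has {rows.size} pixels; at least 5 required")
    (cx, cy), a, b, theta = _moment_ellipse(rows, cols)
    if b <= 1e-9:
        raise ValueError("degenerate (collinear) region; no ellipse fit")
    return EllipseRegion(cx, cy, a, b, theta, scale, marker_type, fitness)


def rasterize_ellipse(ellipse: EllipseRegion, shape: tuple) -> tuple:
    """Pixel coordinates (rows, cols) inside the ellipse, clipped to frame."""
    h, w = shape
    a, b = ellipse.semi_major, ellipse.semi_minor
    cx, cy, th = ellipse.center_x, ellipse.center_y, ellipse.orientation
    r0 = max(int(np.floor(cy - a)), 0)
    r1 = min(int(np.ceil(cy + a)) + 1, h)
    c0 = max(int(np.floor(cx - a)), 0)
    c1 = min(int(np.ceil(cx + a)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx
    dy = yy - cy
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rows, cols = np.nonzero(inside)
    return rows + r0, cols + c0


def extract_candidates(
    label_map,
    pre: PreprocessedImage,
    band_width: int = DEFAULT_BAND_WIDTH,
    ranges: FeatureRanges = DEFAULT_FEATURE_RANGES,
):
    """Feature-filter every region of a watershed label map; fit survivors.

    Returns a list of :class:`EllipseRegion`. Regions failing any feature
    range, the per-scale area bounds, or the ellipse-fit preconditions are
    dropped.
    """
    labels = label_map.labels
    n = label_map.scale
    accepted = []
    objects = ndi.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # quick area screen on the bounding box before full feature work
        full = np.zeros(labels.shape, dtype=bool)
        full[sl] = labels[sl] == idx
        feats = compute_region_features(full, pre, band_width)
        if not ranges.accepts(feats, n):
            continue
        try:
            ell = fit_ellipse(full, n, label_map.marker_type, feats.solidity)
        except ValueError:
            continue
        accepted.append(ell)
    return accepted


def filter_candidates(
    regions: Sequence, features: Sequence[RegionFeatures], n: int,
    ranges: FeatureRanges = DEFAULT_FEATURE_RANGES,
) -> list:
    """Keep regions whose features fall inside every accepted range.

    ``regions`` and ``features`` are parallel sequences; the accepted
    subset of ``regions`` is returned in input order.
    """
    return [r for r, f in zip(regions, features) if ranges.accepts(f, n)]
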