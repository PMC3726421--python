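"""Foreground/background marker construction and marker-controlled watershed.

Two marker types are used per scale: extended regional minima of the FRST
map (robust for round, clustered nuclei) and regional minima of the
preprocessed image (a fallback for elongated or asymmetric nuclei). The
background marker is the morphological skeleton of the complement of the
foreground markers dilated to the maximal expected nucleus radius. Minima
are imposed at marker locations on the Sobel gradient of the preprocessed
image and the watershed is flooded from the markers, so exactly one region
grows per foreground marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import morphology as skmorph
from skimage.segmentation import watershed as sk_watershed

from .frst import SymmetryMap
from .morphology import (
    PreprocessedImage,
    extended_regional_minima,
    label_minima,
    regional_minima,
    skeletonize,
)

__all__ = [
    "MarkerSet",
    "WatershedLabelMap",
    "MarkersTooDenseError",
    "extract_frst_markers",
    "extract_minima_markers",
    "build_background_marker",
    "impose_minima",
    "watershed_with_markers",
]


class MarkersTooDenseError(RuntimeError):
    """Foreground markers dilated to maximal nucleus size cover the frame."""


@dataclass(frozen=True)
class MarkerSet:
    """Labeled foreground markers plus a background skeleton mask."""

    foreground: np.ndarray  # int labels, 0 = non-marker
    background: np.ndarray  # bool skeleton mask
    marker_type: str  # "frst" | "minima"
    scale: int

    def __post_init__(self) -> None:
        if self.marker_type not in ("frst", "minima"):
            raise ValueError(f"unknown marker type {self.marker_type!r}")
        if np.any((self.foreground > 0) & self.background):
            raise ValueError("foreground and background markers overlap")
        if not self.background.any():
            raise ValueError("background marker is empty")

    @property
    def n_markers(self) -> int:
        return int(self.foreground.max())


@dataclass(frozen=True)
class WatershedLabelMap:
    """Watershed output: one labeled region per foreground marker.

    Label 0 covers ridge pixels and the region grown from the background
    marker.
    """

    labels: np.ndarray
    marker_type: str
    scale: int

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


def extract_frst_markers(sym: SymmetryMap, h: float = 0.4) -> np.ndarray:
    """Foreground markers: extended regional minima of the normalized FRST.

    ``h`` is the basin-depth threshold on the [0, 1]-normalized map. A
    constant map yields no markers.
    """
    norm = sym.normalized
    if norm.max() == norm.min():
        return np.zeros(norm.shape, dtype=np.int32)
    mask = extended_regional_minima(norm, h)
    labels, _ = label_minima(mask)
    return labels


def extract_minima_markers(pre: PreprocessedImage) -> np.ndarray:
    """Foreground markers: regional minima of the preprocessed image.

    Components touching the image border and components larger than the
    maximal nucleus area at this scale (4 * n^2 * pi) are discarded — both
    are background plateaus rather than nuclei.
    """
    img = pre.pixels
    n = pre.scale
    mask = regional_minima(img)
    labels, count = label_minima(mask)
    if count == 0:
        return labels.astype(np.int32)

    max_area = 4.0 * np.pi * n * n
    border = np.zeros(img.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = np.unique(labels[border & mask])

    areas = np.bincount(labels.ravel(), minlength=count + 1)
    keep = np.ones(count + 1, dtype=bool)
    keep[0] = False
    keep[areas > max_area] = False
    keep[border_labels[border_labels > 0]] = False

    relabel = np.zeros(count + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, int(keep.sum()) + 1)
    return relabel[labels]


def build_background_marker(markers: np.ndarray, n: int) -> np.ndarray:
    """Skeleton of the provisional background map.

    Each foreground marker is assumed to mark a nucleus of maximal size
    (radius ``2n``, the largest radius in the FRST set). The union of
    markers is dilated by disk(2n); the complement is the provisional
    background, and its skeleton is returned as a thin background marker
    guaranteed to stay off every possible nucleus.
    """
    fg = np.asarray(markers) > 0
    if not fg.any():
        raise ValueError("at least one foreground marker is required")
    # dilation by disk(2n) computed as an exact Euclidean distance threshold
    dilated = ndi.distance_transform_edt(~fg) <= 2 * n
    background_map = ~dilated
    if not background_map.any():
        raise MarkersTooDenseError(
            f"foreground markers dilated by disk({2 * n}) cover the whole "
            "frame; markers too dense for this scale"
        )
    return skeletonize(background_map)


def impose_minima(img: np.ndarray, marker_mask: np.ndarray) -> np.ndarray:
    """Force regional minima of ``img`` to lie exactly at ``marker_mask``.

    Standard reconstruction construction: the marker image is a floor value
    at marker pixels and a ceiling elsewhere; reconstruction by erosion of
    that seed over ``min(img + delta, seed)`` returns a surface whose only
    regional minima are the marker components.
    """
    img = np.asarray(img, dtype=float)
    marker_mask = np.asarray(marker_mask, dtype=bool)
    if not marker_mask.any():
        raise ValueError("marker mask is empty")
    delta = (img.max() - img.min()) / 1000.0 or 1.0
    floor = img.min() - delta
    ceil = img.max() + delta
    seed = np.where(marker_mask, floor, ceil)
    mask = np.minimum(img + delta, seed)
    return skmorph.reconstruction(seed, mask, method="erosion")


def watershed_with_markers(
    pre: PreprocessedImage, markers: MarkerSet
) -> WatershedLabelMap:
    """Marker-controlled watershed on the Sobel gradient of ``pre``.

    The gradient magnitude serves as the segmentation function; minima are
    imposed at the foreground and background marker pixels, the watershed
    floods one region per marker, and the background-grown region is
    discarded (set to 0 along with ridge pixels).
    """
    if markers.foreground.shape != pre.pixels.shape:
        raise ValueError("marker set does not match image dimensions")
    grad = skfilters.sobel(pre.pixels)
    marker_mask = (markers.foreground > 0) | markers.background
    surface = impose_minima(grad, marker_mask)

    n_fg = markers.n_markers
    seeds = markers.foreground.astype(np.int32).copy()
    seeds[markers.background] = n_fg + 1
    labels = sk_watershed(surface, markers=seeds, connectivity=2, watershed_line=True)
    labels[labels == n_fg + 1] = 0
    return WatershedLabelMap(labels.astype(np.int32), markers.marker_type, pre.scale)
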