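"""Reconstruction-based morphological simplification and minima operators.

The hematoxylin image is simplified at a scale ``n`` (the radius, in pixels,
of a disk-shaped structuring element): opening by reconstruction removes
bright structures smaller than the disk, closing by reconstruction removes
dark ones, and a final plain closing with a half-radius disk smooths small
protrusions without moving the main nuclear contours. Varying ``n`` over
the expected range of nuclear minor semi-axes gives the multiscale
decomposition that the segmentation stage consumes.

All operators use 8-connectivity and replicate ("nearest") border padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

__all__ = [
    "disk_footprint",
    "reconstruct_open",
    "reconstruct_close",
    "preprocess_at_scale",
    "h_minima_transform",
    "regional_minima",
    "extended_regional_minima",
    "label_minima",
    "skeletonize",
    "PreprocessedImage",
]

#: 8-connectivity structure used for every connected-component operation.
STRUCTURE_8 = np.ones((3, 3), bool)


def disk_footprint(radius: int) -> np.ndarray:
    """Discrete Euclidean disk: pixels with center distance <= radius."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    return skmorph.disk(radius)


def _check_radius(img: np.ndarray, radius: int) -> None:
    if radius > min(img.shape) // 2:
        raise ValueError(
            f"structuring element radius {radius} exceeds half the smallest "
            f"image extent {min(img.shape)}"
        )


def reconstruct_open(img: np.ndarray, radius: int) -> np.ndarray:
    """Opening by reconstruction: erode by a disk, reconstruct by dilation.

    Removes bright connected structures smaller than the disk while exactly
    preserving the contours of the survivors. Result <= input pixelwise.
    """
    img = np.asarray(img, dtype=float)
    _check_radius(img, radius)
    seed = ndi.grey_erosion(img, footprint=disk_footprint(radius), mode="nearest")
    return skmorph.reconstruction(seed, img, method="dilation")


def reconstruct_close(img: np.ndarray, radius: int) -> np.ndarray:
    """Closing by reconstruction (dual of :func:`reconstruct_open`).

    Removes dark connected structures smaller than the disk.
    Result >= input pixelwise.
    """
    img = np.asarray(img, dtype=float)
    _check_radius(img, radius)
    seed = ndi.grey_dilation(img, footprint=disk_footprint(radius), mode="nearest")
    return skmorph.reconstruction(seed, img, method="erosion")


def plain_closing(img: np.ndarray, radius: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    fp = disk_footprint(radius)
    return ndi.grey_erosion(
        ndi.grey_dilation(img, footprint=fp, mode="nearest"),
        footprint=fp,
        mode="nearest",
    )


@dataclass(frozen=True)
class PreprocessedImage:
    """Grayscale image simplified at one structuring-element scale."""

    pixels: np.ndarray
    scale: int

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")


def preprocess_at_scale(hematoxylin: np.ndarray, n: int) -> PreprocessedImage:
    """Simplify the hematoxylin image at scale ``n``.

    Opening by reconstruction with disk(n), closing by reconstruction with
    disk(n), then a plain morphological closing with disk(round(n / 2)).
    """
    if n < 2:
        raise ValueError(f"scale n must be >= 2, got {n}")
    img = np.asarray(hematoxylin, dtype=float)
    out = reconstruct_open(img, n)
    out = reconstruct_close(out, n)
    out = plain_closing(out, int(round(n / 2)))
    return PreprocessedImage(out, n)


def h_minima_transform(img: np.ndarray, h: float) -> np.ndarray:
    """Suppress all regional minima of depth less than ``h``.

    Grayscale reconstruction by erosion of ``img + h`` over ``img``. The
    output satisfies ``img <= out <= img + h`` pixelwise; basins shallower
    than ``h`` are filled flat, deeper basins lose exactly ``h`` of depth.
    """
    if h < 0:
        raise ValueError(f"depth h must be >= 0, got {h}")
    img = np.asarray(img, dtype=float)
    if h == 0:
        return img.copy()
    return skmorph.reconstruction(img + h, img, method="erosion")


def regional_minima(img: np.ndarray) -> np.ndarray:
    """Boolean mask of regional minima (8-connectivity).

    A regional minimum is a flat connected zone none of whose neighbors is
    lower; a constant image is one minimum covering the whole frame.
    """
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        return np.ones(img.shape, dtype=bool)
    return skmorph.local_minima(img, connectivity=2)


def extended_regional_minima(img: np.ndarray, h: float) -> np.ndarray:
    """Regional minima of the h-minima transform: basins deeper than ``h``."""
    if h <= 0:
        raise ValueError(f"depth h must be > 0, got {h}")
    return regional_minima(h_minima_transform(img, h))


def label_minima(mask: np.ndarray):
    """Label a boolean marker mask with 8-connected components."""
    labels, count = ndi.label(mask, structure=STRUCTURE_8)
    return labels, count


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px topological skeleton (subset of mask)."""
    mask = np.asarray(mask, dtype=bool)
    return skmorph.skeletonize(mask)
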