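"""Orientation-only fast radial symmetry transform (FRST).

The FRST infers centers of radial symmetry by letting every edge pixel vote
along its gradient direction. The orientation-only variant drops the
gradient magnitude from the vote, which makes it robust to low contrast
between nuclei and background. Only the dark-polarity votes are
accumulated: in a hematoxylin image nuclei are dark, their boundary
gradients point outward, and the negatively-affected pixel
``p - round(r * g_hat)`` lands near the nucleus center.

The returned map is sign-flipped so that centers of dark radially symmetric
blobs are *minima*; markers are then extracted as extended regional minima
of the normalized map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["SymmetryMap", "frst_orientation_only", "radius_set_for_scale"]


@dataclass(frozen=True)
class SymmetryMap:
    """FRST response with nucleus centers as minima.

    Attributes
    ----------
    raw
        Real-valued response (negated mean vote image); more negative means
        more radially symmetric dark content.
    normalized
        Min-max rescaled copy in [0, 1] (all zeros for a constant raw map).
    radii
        Radius set the transform was computed over.
    """

    raw: np.ndarray
    normalized: np.ndarray
    radii: tuple


def radius_set_for_scale(n: int) -> tuple:
    """Radius set {n, n+1, ..., 2n} matched to preprocessing scale ``n``."""
    return tuple(range(n, 2 * n + 1))


def frst_orientation_only(
    img: np.ndarray,
    radii,
    alpha: float = 2.0,
    grad_floor: float = 0.05,
    kappa: float = 9.9,
    gaussian_factor: float = 0.5,
) -> SymmetryMap:
    """Compute the orientation-only FRST over a radius set.

    Parameters
    ----------
    img
        Grayscale image (dark blobs are the targets).
    radii
        Strictly increasing integer radii in pixels.
    alpha
        Radial strictness; higher values sharpen the response around true
        centers of symmetry.
    grad_floor
        Pixels whose Sobel gradient magnitude is below this fraction of the
        maximum magnitude cast no vote.
    kappa
        Vote-count clamp before normalization.
    gaussian_factor
        The per-radius smoothing Gaussian has sigma = gaussian_factor * r.
    """
    radii = tuple(int(r) for r in radii)
    if len(radii) == 0:
        raise ValueError("radius set must be non-empty")
    if any(r < 1 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing positive integers")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not 0 <= grad_floor < 1:
        raise ValueError("grad_floor must lie in [0, 1)")

    img = np.asarray(img, dtype=float)
    h, w = img.shape
    gy = ndi.sobel(img, axis=0, mode="nearest")
    gx = ndi.sobel(img, axis=1, mode="nearest")
    mag = np.hypot(gx, gy)
    mag_max = mag.max()

    if mag_max == 0:
        raw = np.zeros_like(img)
        return SymmetryMap(raw, np.zeros_like(img), radii)

    sel = mag > grad_floor * mag_max
    ys, xs = np.nonzero(sel)
    m = mag[sel]
    uy = gy[sel] / m
    ux = gx[sel] / m

    acc = np.zeros((h, w), dtype=float)
    for r in radii:
        # dark-polarity vote: step against the gradient toward the blob core
        py = ys - np.rint(r * uy).astype(np.intp)
        px = xs - np.rint(r * ux).astype(np.intp)
        inside = (py >= 0) & (py < h) & (px >= 0) & (px < w)
        votes = np.bincount(py[inside] * w + px[inside], minlength=h * w)
        o = np.minimum(votes.astype(float), kappa).reshape(h, w)
        f = (o / kappa) ** alpha
        acc += ndi.gaussian_filter(f, sigma=gaussian_factor * r, mode="nearest")

    raw = -acc / len(radii)
    span = raw.max() - raw.min()
    if span == 0:
        normalized = np.zeros_like(raw)
    else:
        normalized = (raw - raw.min()) / span
    return SymmetryMap(raw, normalized, radii)
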