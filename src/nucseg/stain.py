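"""Hematoxylin/eosin stain separation by Lambert-Beer optical-density unmixing.

Bright-field H&E image formation follows the Lambert-Beer law: the
transmitted intensity in detection channel ``k`` is

    I_k = I0_k * 10 ** (-sum_s M[k, s] * c_s)

where ``M`` holds the per-channel absorption coefficients of each stain and
``c_s`` is the local stain concentration. Because optical density
``OD = -log10(I / I0)`` is linear in the concentrations, a 3x3 linear system
per pixel recovers hematoxylin and eosin concentration maps from an RGB
tile. Nuclei take up hematoxylin, so the re-rendered hematoxylin-only image
(converted to grayscale) shows nuclei as dark objects on a bright
background; that image drives all downstream segmentation stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainVectors",
    "rgb_to_optical_density",
    "unmix_stains",
    "hematoxylin_grayscale",
]

#: Rec.709 luminance weights used to collapse the re-rendered stain image.
LUMINANCE_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])

#: Standard published H&E absorption coefficients (per RGB channel, unnormalized).
HEMATOXYLIN_RGB = (0.65, 0.70, 0.29)
EOSIN_RGB = (0.07, 0.99, 0.11)

#: Relative clamp applied to intensities before the log so OD stays finite.
OD_CLAMP_FRACTION = 1.0 / 255.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector has zero norm")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Absorption-coefficient matrix for a stain pair plus residual channel.

    Parameters
    ----------
    matrix
        3x3 array; columns are the unit-norm absorption vectors of
        hematoxylin, eosin and the residual channel (in that order), rows
        are the R, G, B detection channels.
    background
        Per-channel incident ("white") intensity ``I0``.
    """

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(3, 255.0))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("stain coefficients must be non-negative")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("each stain column must have unit Euclidean norm")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (3,) or np.any(bg <= 0):
            raise ValueError("background intensity must be 3 positive values")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @classmethod
    def from_pair(
        cls,
        hematoxylin=HEMATOXYLIN_RGB,
        eosin=EOSIN_RGB,
        background=(255.0, 255.0, 255.0),
    ) -> "StainVectors":
        """Build a full matrix from two stain vectors.

        The residual column is completed as the normalized cross product of
        the two stain vectors with negative components clipped to zero, so
        the matrix stays non-negative and invertible.
        """
        h = _unit(np.asarray(hematoxylin, dtype=float))
        e = _unit(np.asarray(eosin, dtype=float))
        r = np.cross(h, e)
        r = np.clip(r, 0.0, None)
        if np.linalg.norm(r) == 0:
            raise ValueError("hematoxylin and eosin vectors are collinear")
        r = _unit(r)
        return cls(np.column_stack([h, e, r]), np.asarray(background, dtype=float))

    @property
    def inverse(self) -> np.ndarray:
        det = np.linalg.det(self.matrix)
        if abs(det) < 1e-10:
            raise ValueError(
                "stain matrix is singular; hematoxylin/eosin/residual columns "
                "are linearly dependent"
            )
        return np.linalg.inv(self.matrix)


DEFAULT_STAIN_VECTORS = StainVectors.from_pair()


def _check_rgb(tile: np.ndarray) -> np.ndarray:
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image of shape (H, W, 3), got shape {tile.shape}"
        )
    return tile.astype(float)


def rgb_to_optical_density(tile: np.ndarray, i0=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Convert an 8-bit RGB tile to per-channel optical density.

    ``OD = -log10(max(I, eps) / I0)`` with ``eps = I0 / 255`` so saturated
    black pixels map to the finite ceiling ``log10(255) ~= 2.41``. Negative
    densities (pixels brighter than the background) are clipped to zero.
    """
    tile = _check_rgb(tile)
    i0 = np.asarray(i0, dtype=float).reshape(1, 1, 3)
    if np.any(i0 <= 0):
        raise ValueError("background intensity must be positive")
    clamped = np.maximum(tile, i0 * OD_CLAMP_FRACTION)
    od = -np.log10(clamped / i0)
    return np.clip(od, 0.0, None)


def unmix_stains(od: np.ndarray, vectors: StainVectors = DEFAULT_STAIN_VECTORS):
    """Solve the per-pixel 3x3 system for stain concentrations.

    Returns
    -------
    (hematoxylin, eosin) : tuple of 2-D float arrays
        Concentration maps; negative solutions are clipped to zero.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an OD image of shape (H, W, 3), got {od.shape}")
    conc = od @ vectors.inverse.T
    conc = np.clip(conc, 0.0, None)
    return conc[..., 0], conc[..., 1]


def render_stain(
    concentration: np.ndarray,
    stain_vector: np.ndarray,
    i0=(255.0, 255.0, 255.0),
) -> np.ndarray:
    """Forward-render a single-stain RGB image from a concentration map."""
    concentration = np.asarray(concentration, dtype=float)
    od = concentration[..., None] * np.asarray(stain_vector, dtype=float)
    i0 = np.asarray(i0, dtype=float).reshape(1, 1, 3)
    img = i0 * np.power(10.0, -od)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def hematoxylin_grayscale(
    tile: np.ndarray, vectors: StainVectors = DEFAULT_STAIN_VECTORS
) -> np.ndarray:
    """Grayscale hematoxylin single-stain image (nuclei dark), uint8.

    The tile is unmixed, the hematoxylin-only RGB image is re-rendered
    through the Lambert-Beer law from the hematoxylin concentration alone,
    and collapsed to grayscale with Rec.709 luminance weights.
    """
    od = rgb_to_optical_density(tile, vectors.background)
    c_h, _ = unmix_stains(od, vectors)
    rgb = render_stain(c_h, vectors.matrix[:, 0], vectors.background)
    gray = rgb.astype(float) @ LUMINANCE_WEIGHTS
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def hematoxylin_concentration(
    tile: np.ndarray, vectors: StainVectors = DEFAULT_STAIN_VECTORS
) -> np.ndarray:
    """Alternative output: the raw hematoxylin concentration map."""
    od = rgb_to_optical_density(tile, vectors.background)
    c_h, _ = unmix_stains(od, vectors)
    return c_h
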