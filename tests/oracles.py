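"""Independent brute-force oracles for the morphological and set operators.

These are deliberately naive, definition-level implementations (iterated
neighborhood passes, pure-Python flood fills, Python set arithmetic) used
only to cross-check the production code paths.
"""

from __future__ import annotations

import numpy as np


def _shift_max(img: np.ndarray) -> np.ndarray:
    """Max over the 8-neighborhood plus self, replicate borders."""
    p = np.pad(img, 1, mode="edge")
    out = img.copy()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out = np.maximum(out, p[1 + dr : 1 + dr + img.shape[0], 1 + dc : 1 + dc + img.shape[1]])
    return out


def _shift_min(img: np.ndarray) -> np.ndarray:
    p = np.pad(img, 1, mode="edge")
    out = img.copy()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out = np.minimum(out, p[1 + dr : 1 + dr + img.shape[0], 1 + dc : 1 + dc + img.shape[1]])
    return out


def reconstruction_by_dilation(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Iterate geodesic dilation of seed under mask to stability."""
    rec = np.asarray(seed, dtype=float).copy()
    mask = np.asarray(mask, dtype=float)
    while True:
        nxt = np.minimum(_shift_max(rec), mask)
        if np.array_equal(nxt, rec):
            return rec
        rec = nxt


def reconstruction_by_erosion(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Iterate geodesic erosion of seed above mask to stability."""
    rec = np.asarray(seed, dtype=float).copy()
    mask = np.asarray(mask, dtype=float)
    while True:
        nxt = np.maximum(_shift_min(rec), mask)
        if np.array_equal(nxt, rec):
            return rec
        rec = nxt


def h_minima(img: np.ndarray, h: float) -> np.ndarray:
    return reconstruction_by_erosion(np.asarray(img, float) + h, img)


def regional_minima(img: np.ndarray) -> np.ndarray:
    """Flood every flat plateau; mark it iff no 8-neighbor is lower."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    visited = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for r0 in range(h):
        for c0 in range(w):
            if visited[r0, c0]:
                continue
            val = img[r0, c0]
            stack = [(r0, c0)]
            plateau = []
            visited[r0, c0] = True
            is_min = True
            while stack:
                r, c = stack.pop()
                plateau.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w):
                            continue
                        if img[rr, cc] < val:
                            is_min = False
                        elif img[rr, cc] == val and not visited[rr, cc]:
                            visited[rr, cc] = True
                            stack.append((rr, cc))
            if is_min:
                for r, c in plateau:
                    out[r, c] = True
    return out


def dice(x, y) -> float:
    sx, sy = set(map(int, x)), set(map(int, y))
    return 2.0 * len(sx & sy) / (len(sx) + len(sy))


def overlap(x, y) -> float:
    sx, sy = set(map(int, x)), set(map(int, y))
    return len(sx & sy) / min(len(sx), len(sy))


def frst_vote_accumulation(img: np.ndarray, radii, grad_floor: float = 0.05):
    """Plain per-pixel loop accumulating dark-polarity orientation votes.

    Returns the raw (unclamped, unsmoothed) vote count image summed over
    the radius set — enough to locate the strongest symmetry center.
    """
    from scipy import ndimage as ndi

    img = np.asarray(img, dtype=float)
    h, w = img.shape
    gy = ndi.sobel(img, axis=0, mode="nearest")
    gx = ndi.sobel(img, axis=1, mode="nearest")
    mag = np.hypot(gx, gy)
    floor = grad_floor * mag.max()
    votes = np.zeros((h, w))
    for r in radii:
        for y in range(h):
            for x in range(w):
                m = mag[y, x]
                if m <= floor:
                    continue
                py = y - int(round(r * gy[y, x] / m))
                px = x - int(round(r * gx[y, x] / m))
                if 0 <= py < h and 0 <= px < w:
                    votes[py, px] += 1
    return votes
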