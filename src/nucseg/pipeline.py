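"""End-to-end multiscale, multimarker nuclei segmentation pipeline.

For every structuring-element scale ``n`` in the configured set, the
hematoxylin image is morphologically simplified and segmented twice — once
from FRST markers, once from regional-minima markers. Each segmentation is
feature-filtered and ellipse-standardized, all candidates from all scales
and marker types are pooled, and conflicts are resolved greedily by
solidity fitness. The whole pipeline is deterministic: the same tile and
config reproduce the same result bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .features import (
    DEFAULT_BAND_WIDTH,
    EllipseRegion,
    FeatureRanges,
    extract_candidates,
    rasterize_ellipse,
)
from .frst import frst_orientation_only, radius_set_for_scale
from .merge import CandidatePool, DEFAULT_OVERLAP_THRESHOLD, resolve_overlaps
from .morphology import preprocess_at_scale
from .stain import HEMATOXYLIN_RGB, EOSIN_RGB, StainVectors, hematoxylin_grayscale
from .watershed import (
    MarkerSet,
    MarkersTooDenseError,
    build_background_marker,
    extract_frst_markers,
    extract_minima_markers,
    watershed_with_markers,
)

__all__ = ["PipelineConfig", "SegmentationResult", "segment_image"]

logger = logging.getLogger("nucseg")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters with their default values.

    The defaults encode the standard operating point for x40 (0.25 um/px)
    breast H&E tiles: scales 10..18 px (the expected range of nuclear minor
    semi-axes), FRST basin depth h = 0.4, feature ranges
    s in (0.875, 1) / l in (20, 255) / d in [0, 0.08], and merge overlap
    threshold 0.2.
    """

    hematoxylin_rgb: Tuple[float, float, float] = HEMATOXYLIN_RGB
    eosin_rgb: Tuple[float, float, float] = EOSIN_RGB
    background_intensity: Tuple[float, float, float] = (255.0, 255.0, 255.0)
    scales: Tuple[int, ...] = tuple(range(10, 19))
    marker_types: Tuple[str, ...] = ("frst", "minima")
    frst_alpha: float = 2.0
    frst_kappa: float = 9.9
    frst_gaussian_factor: float = 0.5
    frst_grad_floor: float = 0.05
    frst_h: float = 0.4
    solidity_range: Tuple[float, float] = (0.875, 1.0)
    saliency_range: Tuple[float, float] = (20.0, 255.0)
    displacement_range: Tuple[float, float] = (0.0, 0.08)
    band_width: int = DEFAULT_BAND_WIDTH
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD

    def __post_init__(self) -> None:
        if list(self.scales) != sorted(set(self.scales)) or min(self.scales, default=2) < 2:
            raise ValueError("scales must be strictly increasing integers >= 2")
        for t in self.marker_types:
            if t not in ("frst", "minima"):
                raise ValueError(f"unknown marker type {t!r}")

    @property
    def stain_vectors(self) -> StainVectors:
        return StainVectors.from_pair(
            self.hematoxylin_rgb, self.eosin_rgb, self.background_intensity
        )

    @property
    def feature_ranges(self) -> FeatureRanges:
        return FeatureRanges(
            self.solidity_range, self.saliency_range, self.displacement_range
        )

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()},
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        kw = {}
        for k, v in data.items():
            kw[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)


@dataclass(frozen=True)
class SegmentationResult:
    """Final merged set of elliptical nucleus regions."""

    ellipses: List[EllipseRegion]
    shape: Tuple[int, int]
    per_scale_counts: dict = field(default_factory=dict)

    @property
    def n_nuclei(self) -> int:
        return len(self.ellipses)

    def label_map(self) -> np.ndarray:
        """Rasterize accepted ellipses; earlier-accepted regions keep
        contested pixels (accepted pairs may overlap by OV <= threshold)."""
        labels = np.zeros(self.shape, dtype=np.uint16)
        for i, ell in enumerate(self.ellipses, start=1):
            rr, cc = rasterize_ellipse(ell, self.shape)
            fresh = labels[rr, cc] == 0
            labels[rr[fresh], cc[fresh]] = i
        return labels

    def pixel_sets(self) -> List[np.ndarray]:
        """Flat pixel-index set of each accepted ellipse (full raster)."""
        w = self.shape[1]
        out = []
        for ell in self.ellipses:
            rr, cc = rasterize_ellipse(ell, self.shape)
            out.append(np.sort(rr.astype(np.int64) * w + cc))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            dict(
                id=i,
                center_x=e.center_x,
                center_y=e.center_y,
                semi_major=e.semi_major,
                semi_minor=e.semi_minor,
                orientation_rad=e.orientation,
                scale_n=e.scale,
                marker_type=e.marker_type,
                solidity=e.fitness,
            )
            for i, e in enumerate(self.ellipses, start=1)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id",
                "center_x",
                "center_y",
                "semi_major",
                "semi_minor",
                "orientation_rad",
                "scale_n",
                "marker_type",
                "solidity",
            ],
        )


def _candidates_at_scale(
    hema: np.ndarray, n: int, cfg: PipelineConfig
) -> List[EllipseRegion]:
    pre = preprocess_at_scale(hema, n)
    out: List[EllipseRegion] = []
    for marker_type in cfg.marker_types:
        if marker_type == "frst":
            sym = frst_orientation_only(
                pre.pixels,
                radius_set_for_scale(n),
                alpha=cfg.frst_alpha,
                grad_floor=cfg.frst_grad_floor,
                kappa=cfg.frst_kappa,
                gaussian_factor=cfg.frst_gaussian_factor,
            )
            fg = extract_frst_markers(sym, cfg.frst_h)
        else:
            fg = extract_minima_markers(pre)
        if fg.max() == 0:
            logger.info("scale %d/%s: no foreground markers", n, marker_type)
            continue
        try:
            bg = build_background_marker(fg, n)
        except MarkersTooDenseError:
            logger.info("scale %d/%s: markers too dense, skipped", n, marker_type)
            continue
        markers = MarkerSet(fg, bg, marker_type, n)
        label_map = watershed_with_markers(pre, markers)
        cands = extract_candidates(label_map, pre, cfg.band_width, cfg.feature_ranges)
        logger.info(
            "scale %d/%s: %d markers -> %d regions -> %d accepted",
            n,
            marker_type,
            markers.n_markers,
            label_map.n_regions,
            len(cands),
        )
        out.extend(cands)
    return out


def segment_image(tile: np.ndarray, cfg: Optional[PipelineConfig] = None) -> SegmentationResult:
    """Run the full multiscale, multimarker segmentation on an RGB tile."""
    cfg = cfg or PipelineConfig()
    vectors = cfg.stain_vectors
    hema = hematoxylin_grayscale(tile, vectors)

    pool_candidates: List[EllipseRegion] = []
    counts = {}
    for n in cfg.scales:
        try:
            cands = _candidates_at_scale(hema, n, cfg)
        except Exception as exc:  # annotate failures with stage context
            raise RuntimeError(f"segmentation failed at scale n={n}: {exc}") from exc
        counts[n] = len(cands)
        pool_candidates.extend(cands)

    if not pool_candidates:
        return SegmentationResult([], hema.shape, counts)
    pool = CandidatePool(pool_candidates, hema.shape)
    accepted = resolve_overlaps(pool, cfg.overlap_threshold)
    return SegmentationResult(accepted, hema.shape, counts)
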