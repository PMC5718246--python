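"""Candidate puncta segmentation: pre-filter, three thresholds, dilation,
gradient-based background removal, watershed splitting, size discrimination,
and cross-threshold deduplication.

Thresholding uses three fixed fractional levels (defaults equivalent to
8-bit grayscale 30, 70 and 220), producing nested binary masks; each mask is
labeled separately and the per-level label images are later flattened so every
punctum is represented once, by the highest threshold that detected it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.segmentation import watershed

from .errors import ConfigError, PunctaError
from .image_io import PixelScale

# 8-connectivity for component labeling throughout
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable segmentation parameters.

    ``thresholds`` are fractions of full scale; the defaults correspond to
    8-bit grayscale values 30, 70 and 220. ``background_removal_factor`` is the
    minimum mean first-gradient magnitude (0-1 scale) an ROI must exceed to
    survive; raise it (e.g. to 0.25) for high-background images. The area band
    ``[min_area_um2, max_area_um2]`` defaults to [0.16, 6.25] um^2, bracketing
    the 0.4-4 um diameter range typical of confocal protein puncta.
    """

    thresholds: tuple[float, float, float] = (30 / 255, 70 / 255, 220 / 255)
    background_removal_factor: float = 0.175
    prefilter_enabled: bool = True
    watershed_enabled: bool = True
    min_area_um2: float = 0.16
    max_area_um2: float = 6.25

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) != 3 or not all(0.0 < a < 1.0 for a in t) or not (t[0] < t[1] < t[2]):
            raise ConfigError(f"thresholds must be 3 ascending values in (0,1), got {t}")
        if not 0.0 <= self.background_removal_factor <= 1.0:
            raise ConfigError("background_removal_factor must lie in [0,1]")
        if not 0.0 < self.min_area_um2 < self.max_area_um2:
            raise ConfigError("need 0 < min_area_um2 < max_area_um2")


@dataclass
class ThresholdMasks:
    """The three binary images, level 1 = lowest threshold."""

    level_masks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.level_masks) != 3:
            raise PunctaError("expected exactly 3 threshold levels")


@dataclass
class LabelImage:
    """Integer-labeled ROI map; ``provenance[k]`` is the threshold level that
    produced ROI ``k``. Labels are always a contiguous 1..K range."""

    labels: np.ndarray
    provenance: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise PunctaError("label image must be 2-D")

    @property
    def n_rois(self) -> int:
        return int(self.labels.max(initial=0))

    def roi_ids(self) -> list[int]:
        return list(range(1, self.n_rois + 1))


def _relabel(labels: np.ndarray, keep: np.ndarray, provenance: dict[int, int]) -> LabelImage:
    """Keep the ROIs whose (1-based) ids are in ``keep``; renumber 1..K
    preserving the original order."""
    keep = np.asarray(sorted(keep), dtype=np.int64)
    lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    new_prov = {int(lut[k]): provenance[int(k)] for k in keep if int(k) in provenance}
    return LabelImage(labels=lut[labels], provenance=new_prov)


def label_components(mask: np.ndarray, level: int | None = None) -> LabelImage:
    """8-connected component labeling with optional provenance level."""
    labels, n = ndi.label(mask, structure=_STRUCTURE_8)
    prov = {k: level for k in range(1, n + 1)} if level is not None else {}
    return LabelImage(labels=labels.astype(np.int32), provenance=prov)


def prefilter(image: np.ndarray, enabled: bool = True) -> np.ndarray:
    """3x3 median pre-filter (identity when disabled).

    The median is robust to shot noise and preserves punctum edges, which
    matters because the gradient images downstream are edge templates.
    """
    image = np.asarray(image, dtype=np.float64)
    if not enabled:
        return image
    return np.clip(ndi.median_filter(image, size=3, mode="reflect"), 0.0, 1.0)


def multi_threshold(image: np.ndarray, config: SegmentationConfig) -> ThresholdMasks:
    """Apply the three strict thresholds; masks are nested by construction
    (level 3 foreground within level 2 within level 1)."""
    image = np.asarray(image, dtype=np.float64)
    return ThresholdMasks(level_masks=[image > t for t in config.thresholds])


def dilate_mask(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Morphological dilation with a disk structuring element; radius 0 is the
    identity. In the pipeline only the two upper threshold levels are dilated."""
    if radius_px < 0:
        raise ConfigError("dilation radius must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if radius_px == 0:
        return mask.copy()
    return ndi.binary_dilation(mask, structure=disk(radius_px))


def background_filter(labels: LabelImage, gradient_image: np.ndarray, factor: float) -> LabelImage:
    """Drop ROIs whose mean first-gradient magnitude over their filled pixels
    is not strictly above ``factor``.

    True puncta rise sharply above background and decay quickly, producing
    high gradient magnitudes; diffuse background ROIs do not. A flat image has
    zero gradient everywhere, so every ROI fails for any factor >= 0.
    """
    gradient_image = np.asarray(gradient_image, dtype=np.float64)
    if gradient_image.shape != labels.labels.shape:
        raise PunctaError("gradient image shape does not match label image")
    n = labels.n_rois
    if n == 0:
        return LabelImage(labels=labels.labels.copy(), provenance=dict(labels.provenance))
    means = ndi.mean(gradient_image, labels=labels.labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(np.asarray(means) > factor) + 1
    return _relabel(labels.labels, keep, labels.provenance)


def watershed_split(
    mask: np.ndarray,
    intensity: np.ndarray,
    enabled: bool = True,
    level: int | None = None,
    min_seed_distance_px: int = 2,
) -> LabelImage:
    """Label a binary mask, splitting merged blobs at intensity valleys.

    When enabled, seeds are regional maxima of the median-filtered intensity
    within the mask, with maxima closer than ``min_seed_distance_px`` merged
    (mitigates plateau-driven over-splitting); the watershed then floods the
    negated intensity. When disabled, plain 8-connected component labeling.
    """
    mask = np.asarray(mask, dtype=bool)
    if not enabled:
        return label_components(mask, level=level)
    if not mask.any():
        return LabelImage(labels=np.zeros(mask.shape, dtype=np.int32), provenance={})
    smoothed = ndi.median_filter(np.asarray(intensity, dtype=np.float64), size=3, mode="reflect")
    coords = peak_local_max(
        smoothed, labels=mask, min_distance=min_seed_distance_px, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = 1
    # merge seed clusters closer than the minimum distance into one marker
    markers, n_seeds = ndi.label(
        ndi.binary_dilation(markers > 0, structure=disk(min_seed_distance_px)) & mask,
        structure=_STRUCTURE_8,
    )
    if n_seeds == 0:  # plateau with no detected maximum: fall back to components
        return label_components(mask, level=level)
    labels = watershed(-smoothed, markers=markers, mask=mask, connectivity=2)
    # components missed by every seed (can happen with border plateaus)
    orphan = mask & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan, structure=_STRUCTURE_8)
        labels = labels + np.where(extra > 0, extra + n_seeds, 0)
    out = LabelImage(labels=labels.astype(np.int32))
    out = _relabel(out.labels, np.unique(out.labels[out.labels > 0]), {})
    if level is not None:
        out.provenance = {k: level for k in out.roi_ids()}
    return out


def size_filter(
    labels: LabelImage, scale: PixelScale, min_area_um2: float, max_area_um2: float
) -> LabelImage:
    """Remove ROIs whose physical area falls outside the inclusive band
    [min_area_um2, max_area_um2]."""
    n = labels.n_rois
    if n == 0:
        return LabelImage(labels=labels.labels.copy(), provenance=dict(labels.provenance))
    counts = np.bincount(labels.labels.ravel(), minlength=n + 1)[1:]
    areas = counts * scale.pixel_area_um2
    keep = np.flatnonzero((areas >= min_area_um2) & (areas <= max_area_um2)) + 1
    return _relabel(labels.labels, keep, labels.provenance)


def flatten_thresholds(per_level: list[LabelImage]) -> LabelImage:
    """Deduplicate ROIs across threshold levels into one label image.

    A punctum detected at several thresholds appears as spatially overlapping
    ROIs; the retained version is the one from the highest level that detected
    it. Concretely, an ROI at level j is discarded if it shares any pixel with
    any ROI of a higher level. The survivors are disjoint by construction and
    are renumbered 1..K from the highest level down.
    """
    if not per_level:
        raise PunctaError("flatten_thresholds needs at least one level")
    shape = per_level[0].labels.shape
    for li in per_level:
        if li.labels.shape != shape:
            raise PunctaError("all levels must share one shape")

    def level_of(li: LabelImage, default: int) -> dict[int, int]:
        return {k: li.provenance.get(k, default) for k in li.roi_ids()}

    # order level images from highest provenance level to lowest
    tagged = []
    for i, li in enumerate(per_level):
        levels = level_of(li, i + 1)
        tagged.append((max(levels.values(), default=i + 1), li, levels))
    tagged.sort(key=lambda t: -t[0])

    out = np.zeros(shape, dtype=np.int32)
    provenance: dict[int, int] = {}
    higher_union = np.zeros(shape, dtype=bool)
    next_id = 1
    for _, li, levels in tagged:
        survivors = []
        for k in li.roi_ids():
            roi = li.labels == k
            if not (roi & higher_union).any():
                survivors.append((k, roi))
        for k, roi in survivors:
            out[roi] = next_id
            provenance[next_id] = levels[k]
            next_id += 1
        higher_union |= li.labels > 0
    return LabelImage(labels=out, provenance=provenance)


__all__ = [
    "SegmentationConfig", "ThresholdMasks", "LabelImage", "label_components",
    "prefilter", "multi_threshold", "dilate_mask", "background_filter",
    "watershed_split", "size_filter", "flatten_thresholds",
]
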