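"""Per-punctum measurements and per-image summaries, in physical units.

Areas are reported in um^2 (pixel count times pixel area), intensities on the
0-255 display scale regardless of source bit depth (normalization makes 8- and
16-bit rounds commensurable), and centroids as pixel-center positions in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import regionprops

from .errors import PunctaError
from .image_io import PixelScale
from .segmentation import LabelImage

#: Default per-image area histogram: 25 equal bins over [0, 6.25] um^2.
DEFAULT_AREA_BINS = np.linspace(0.0, 6.25, 26)


@dataclass(frozen=True)
class PunctumRecord:
    id: int
    area_um2: float
    mean_intensity_255: float
    centroid_um: tuple[float, float]  # (x, y) in um
    threshold_level: int


@dataclass
class ImageSummary:
    source_path: str
    puncta_count: int
    mean_area_um2: float | None
    mean_intensity_255: float | None
    map2_area_um2: float | None
    largest_soma_area_um2: float | None
    density_per_map2_area: float | None
    area_histogram: np.ndarray = field(default_factory=lambda: np.zeros(25, dtype=int))
    area_bin_edges: np.ndarray = field(default_factory=lambda: DEFAULT_AREA_BINS.copy())


def measure_puncta(
    labels: LabelImage, intensity: np.ndarray, scale: PixelScale
) -> list[PunctumRecord]:
    """One record per ROI: physical area, display-scale mean intensity, and
    unweighted centroid in um."""
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.shape != labels.labels.shape:
        raise PunctaError("intensity and label images must share one shape")
    records: list[PunctumRecord] = []
    for prop in regionprops(labels.labels, intensity_image=intensity):
        row, col = prop.centroid
        records.append(
            PunctumRecord(
                id=int(prop.label),
                area_um2=float(prop.num_pixels) * scale.pixel_area_um2,
                mean_intensity_255=float(prop.intensity_mean) * 255.0,
                centroid_um=(
                    float(col) * scale.microns_per_pixel_x,
                    float(row) * scale.microns_per_pixel_y,
                ),
                threshold_level=int(labels.provenance.get(int(prop.label), 1)),
            )
        )
    return records


def summarize_image(
    records: list[PunctumRecord],
    neurites=None,
    bins: np.ndarray | None = None,
    source_path: str = "",
) -> ImageSummary:
    """Aggregate per-punctum records into the per-image summary row.

    Density is puncta count per um^2 of MAP2-positive area; it is flagged
    undefined (None) when no MAP2 area is available, never silently zero.
    """
    bins = DEFAULT_AREA_BINS if bins is None else np.asarray(bins, dtype=np.float64)
    if bins.ndim != 1 or bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise PunctaError("histogram bins must be ascending edges")
    areas = np.array([r.area_um2 for r in records], dtype=np.float64)
    hist, _ = np.histogram(np.clip(areas, bins[0], bins[-1]), bins=bins)
    count = len(records)
    map2_area = None if neurites is None else float(neurites.dendrite_area_um2)
    density = None
    if map2_area is not None and map2_area > 0:
        density = count / map2_area
    return ImageSummary(
        source_path=source_path,
        puncta_count=count,
        mean_area_um2=float(areas.mean()) if count else None,
        mean_intensity_255=(
            float(np.mean([r.mean_intensity_255 for r in records])) if count else None
        ),
        map2_area_um2=map2_area,
        largest_soma_area_um2=(
            None if neurites is None else float(neurites.largest_soma_area_um2)
        ),
        density_per_map2_area=density,
        area_histogram=hist,
        area_bin_edges=bins.copy(),
    )


def cumulative_fraction(values: list[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and their empirical CDF, for cumulative-fraction plots."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        return v, v
    return v, np.arange(1, v.size + 1) / v.size


__all__ = [
    "PunctumRecord", "ImageSummary", "DEFAULT_AREA_BINS",
    "measure_puncta", "summarize_image", "cumulative_fraction",
]
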