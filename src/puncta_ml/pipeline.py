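"""Per-image orchestration and per-round aggregation.

Stage order for one image: median pre-filter; gradient templates; three
thresholds; per level — gradient background removal on the undilated cores,
watershed splitting, neurite correlation (if configured), size
discrimination; structure-guided trace optimization for threshold levels 2
then 3; cross-threshold flattening; a final size discrimination so optimized
traces cannot exit the physical area band; measurement and summary.

All dilation is owned by the optimization stage (the loop starts at radius 0),
so the background filter always sees undilated cores, whose gradient means are
well defined. The pipeline contains no randomness: identical inputs and config
give bit-identical outputs.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, PunctaError
from .gradients_ml import gradient_pair, optimize_traces
from .image_io import DatasetLayout, MultiChannelImage, PixelScale, load_image
from .measurement import ImageSummary, PunctumRecord, measure_puncta, summarize_image
from .neurite_correlation import (
    DEFAULT_DILATION_MARGIN_UM,
    DEFAULT_SOMA_MIN_AREA_UM2,
    NeuriteMask,
    correlate_puncta,
    segment_neurites,
)
from .segmentation import (
    LabelImage,
    SegmentationConfig,
    background_filter,
    flatten_thresholds,
    multi_threshold,
    prefilter,
    size_filter,
    watershed_split,
)

logger = logging.getLogger(__name__)

CORRELATION_MODES = ("off", "dendrites", "dendrites+soma")


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    ml_enabled: bool = True
    max_dilation_radius_px: int = 10
    map2_correlation: str = "off"
    dilation_margin_um: float = DEFAULT_DILATION_MARGIN_UM
    soma_min_area_um2: float = DEFAULT_SOMA_MIN_AREA_UM2
    include_soma_in_output: bool = True
    objective_mean_mode: str = "edge-pixels"

    def __post_init__(self) -> None:
        if self.map2_correlation not in CORRELATION_MODES:
            raise ConfigError(f"map2_correlation must be one of {CORRELATION_MODES}")
        if self.max_dilation_radius_px < 0:
            raise ConfigError("max_dilation_radius_px must be >= 0")
        if self.dilation_margin_um < 0:
            raise ConfigError("dilation_margin_um must be >= 0")
        if self.objective_mean_mode not in ("edge-pixels", "all-pixels"):
            raise ConfigError("objective_mean_mode must be 'edge-pixels' or 'all-pixels'")


@dataclass
class ImageFailure:
    source_path: str
    stage: str
    message: str


@dataclass
class RoundResults:
    round_name: str
    image_summaries: list[ImageSummary] = field(default_factory=list)
    puncta_tables: list[list[PunctumRecord]] = field(default_factory=list)
    failures: list[ImageFailure] = field(default_factory=list)

    def parameter_values(self, parameter: str) -> np.ndarray:
        """Per-image values of one summary parameter (NaN-free)."""
        key = {
            "count": "puncta_count",
            "area": "mean_area_um2",
            "intensity": "mean_intensity_255",
            "density": "density_per_map2_area",
        }[parameter]
        vals = [getattr(s, key) for s in self.image_summaries]
        return np.array([v for v in vals if v is not None], dtype=np.float64)


def process_image(
    image: MultiChannelImage, config: PipelineConfig | None = None
) -> tuple[ImageSummary, list[PunctumRecord], LabelImage, NeuriteMask | None]:
    """Run the full single-image algorithm; fully deterministic."""
    config = config or PipelineConfig()
    seg = config.segmentation
    scale = image.scale

    filtered = prefilter(image.puncta_channel, seg.prefilter_enabled)
    gradients = gradient_pair(filtered)
    masks = multi_threshold(filtered, seg)

    neurites: NeuriteMask | None = None
    correlate = config.map2_correlation != "off"
    if correlate or config.include_soma_in_output:
        if image.neurite_channel is not None:
            neurites = segment_neurites(
                image.neurite_channel, scale, soma_min_area_um2=config.soma_min_area_um2
            )
            neurites.dilation_margin_um = config.dilation_margin_um
        elif correlate:
            raise PunctaError("MAP2 correlation requested but image has no neurite channel")

    per_level: list[LabelImage] = []
    for level, mask in enumerate(masks.level_masks, start=1):
        labels = watershed_split(mask, filtered, enabled=False, level=level)
        labels = background_filter(labels, gradients.first, seg.background_removal_factor)
        if seg.watershed_enabled:
            labels = watershed_split(labels.labels > 0, filtered, enabled=True, level=level)
        if correlate and neurites is not None:
            labels = correlate_puncta(
                labels,
                neurites,
                scale,
                include_soma=config.map2_correlation == "dendrites+soma",
                margin_um=config.dilation_margin_um,
            )
        labels = size_filter(labels, scale, seg.min_area_um2, seg.max_area_um2)
        if config.ml_enabled and level in (2, 3):
            labels = optimize_traces(
                labels,
                gradients,
                max_radius_px=config.max_dilation_radius_px,
                level=level,
                mean_mode=config.objective_mean_mode,
            )
        per_level.append(labels)

    final = flatten_thresholds(per_level)
    final = size_filter(final, scale, seg.min_area_um2, seg.max_area_um2)

    records = measure_puncta(final, filtered, scale)
    summary = summarize_image(records, neurites=neurites, source_path=image.source_path)
    return summary, records, final, neurites


def process_dataset(
    layout: DatasetLayout,
    config: PipelineConfig | None = None,
    scale: PixelScale | None = None,
    channel_map: dict[str, int] | None = None,
    loaded_images: dict | None = None,
) -> list[RoundResults]:
    """Process every image of every round; one bad image is recorded as a
    failure and never aborts the batch.

    ``loaded_images`` optionally maps path -> MultiChannelImage to process
    in-memory images (used by tests and the simulator); otherwise images are
    read from disk with ``scale`` and ``channel_map``.
    """
    config = config or PipelineConfig()
    if not layout.rounds:
        raise PunctaError("dataset layout is empty")
    results: list[RoundResults] = []
    for round_name, paths in layout.rounds:
        rr = RoundResults(round_name=round_name)
        for path in paths:
            stage = "load"
            try:
                if loaded_images is not None and path in loaded_images:
                    img = loaded_images[path]
                else:
                    if scale is None:
                        raise ConfigError("pixel scale required to load images from disk")
                    img = load_image(path, scale, channel_map=channel_map)
                stage = "process"
                summary, records, _, _ = process_image(img, config)
                rr.image_summaries.append(summary)
                rr.puncta_tables.append(records)
                logger.info("%s/%s: %d puncta", round_name, path, summary.puncta_count)
            except Exception as exc:
                logger.error("failed %s at stage %s: %s", path, stage, exc)
                logger.debug(traceback.format_exc())
                rr.failures.append(ImageFailure(str(path), stage, str(exc)))
        results.append(rr)
    return results


__all__ = [
    "PipelineConfig", "ImageFailure", "RoundResults", "process_image", "process_dataset",
]
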