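"""Reading micrographs, channel mapping, intensity normalization, dataset discovery.

All downstream processing works on intensities normalized to [0, 1]; an 8-bit
pixel value v maps to v/255 and a 16-bit value to v/65535. Pixel coordinates
are 0-based (row, col); physical coordinates are pixel-center positions in
micrometers, derived from a user-supplied :class:`PixelScale` (field extent is
metadata the acquisition software knows, not something stored reliably in the
files themselves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ConfigError, EmptyDatasetError, InputError, UnsupportedInputError

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".tif", ".tiff", ".jpg", ".jpeg"}

#: Default channel roles for RGB inputs: red carries the puncta marker
#: (e.g. synapsin), green the dendrite marker (MAP2).
DEFAULT_RGB_CHANNEL_MAP = {"puncta": 0, "neurite": 1}


@dataclass(frozen=True)
class PixelScale:
    """Physical size of one pixel, per axis, in micrometers."""

    microns_per_pixel_x: float
    microns_per_pixel_y: float

    def __post_init__(self) -> None:
        for v in (self.microns_per_pixel_x, self.microns_per_pixel_y):
            if not (np.isfinite(v) and v > 0):
                raise ConfigError(f"pixel scale must be positive and finite, got {v}")

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in square micrometers."""
        return self.microns_per_pixel_x * self.microns_per_pixel_y


@dataclass
class MultiChannelImage:
    """Normalized-intensity channels of one micrograph plus scale metadata."""

    puncta_channel: np.ndarray
    scale: PixelScale
    neurite_channel: np.ndarray | None = None
    source_path: str = ""
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.puncta_channel = np.asarray(self.puncta_channel, dtype=np.float64)
        if self.puncta_channel.ndim != 2:
            raise InputError("puncta channel must be 2-D")
        if self.neurite_channel is not None:
            self.neurite_channel = np.asarray(self.neurite_channel, dtype=np.float64)
            if self.neurite_channel.shape != self.puncta_channel.shape:
                raise InputError("puncta and neurite channels must share dimensions")
        for ch in (self.puncta_channel, self.neurite_channel):
            if ch is not None and (ch.min() < 0.0 or ch.max() > 1.0):
                raise InputError("channel intensities must lie in [0, 1]")


@dataclass
class DatasetLayout:
    """Ordered rounds (conditions), each a named list of image paths."""

    rounds: list[tuple[str, list[Path]]] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return sum(len(paths) for _, paths in self.rounds)


def compute_pixel_scale(
    field_width_um: float, field_height_um: float, width_px: int, height_px: int
) -> PixelScale:
    """Physical pixel size from the field extent and pixel resolution.

    Example: a 101.6 x 101.6 um field at 1024 x 1024 px gives
    0.09921875 um/px on both axes.
    """
    args = (field_width_um, field_height_um, width_px, height_px)
    if any(a <= 0 for a in args):
        raise ConfigError(f"field dimensions and pixel counts must be positive, got {args}")
    return PixelScale(field_width_um / width_px, field_height_um / height_px)


def _infer_bit_depth(arr: np.ndarray, hint: int | None) -> int:
    if hint is not None:
        if hint not in (8, 16):
            raise ConfigError(f"bit depth hint must be 8 or 16, got {hint}")
        return hint
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise UnsupportedInputError(
        f"cannot infer bit depth from dtype {arr.dtype}; pass bit_depth_hint"
    )


def _read_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            return tifffile.imread(path)
        return iio.imread(path)
    except FileNotFoundError as exc:
        raise InputError(f"image not found: {path}") from exc
    except Exception as exc:  # unreadable / truncated / wrong format
        raise InputError(f"could not read image {path}: {exc}") from exc


def _split_channels(arr: np.ndarray, path: Path) -> list[np.ndarray]:
    """Return the image as a list of 2-D channel planes.

    Accepts (H, W), channel-last (H, W, C<=4) and channel-first (C<=4, H, W)
    layouts. Anything with more planes is treated as a Z-stack and rejected:
    projection choice belongs to acquisition, so users must supply
    maximum-intensity projections themselves.
    """
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        if arr.shape[-1] <= 4:
            return [arr[..., c] for c in range(arr.shape[-1])]
        if arr.shape[0] <= 4:
            return [arr[c] for c in range(arr.shape[0])]
        raise UnsupportedInputError(
            f"{path} looks like a Z-stack ({arr.shape}); provide a "
            "maximum-intensity projection instead"
        )
    raise UnsupportedInputError(
        f"{path} has {arr.ndim} dimensions; provide 2-D single- or multi-channel images"
    )


def load_image(
    path: str | Path,
    scale: PixelScale,
    channel_map: dict[str, int] | None = None,
    bit_depth_hint: int | None = None,
) -> MultiChannelImage:
    """Read a TIFF/JPEG micrograph and normalize the mapped channels to [0, 1].

    Parameters
    ----------
    path:
        TIFF or JPEG file, 2-D, 1-4 channels.
    scale:
        Physical pixel size (the files carry no trustworthy scale metadata).
    channel_map:
        Maps the roles ``"puncta"`` (required) and ``"neurite"`` (optional) to
        channel indices. Defaults to red=puncta, green=neurite for color
        images and channel 0 = puncta for single-channel images.
    bit_depth_hint:
        Force 8 or 16; otherwise inferred from the array dtype.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    arr = _read_array(path)
    channels = _split_channels(arr, path)
    if channel_map is None:
        if len(channels) == 1:
            channel_map = {"puncta": 0}
        else:
            channel_map = dict(DEFAULT_RGB_CHANNEL_MAP)
    if "puncta" not in channel_map:
        raise ConfigError("channel_map must assign a 'puncta' channel")
    for role, idx in channel_map.items():
        if not 0 <= idx < len(channels):
            raise ConfigError(
                f"channel index {idx} for role '{role}' out of range "
                f"(image has {len(channels)} channel(s))"
            )
    if ("neurite" in channel_map
            and channel_map["neurite"] == channel_map["puncta"]):
        raise ConfigError("puncta and neurite must map to distinct channels")

    bit_depth = _infer_bit_depth(channels[0], bit_depth_hint)
    full_scale = float(2**bit_depth - 1)
    puncta = channels[channel_map["puncta"]].astype(np.float64) / full_scale
    neurite = None
    if "neurite" in channel_map:
        neurite = channels[channel_map["neurite"]].astype(np.float64) / full_scale
    return MultiChannelImage(
        puncta_channel=np.clip(puncta, 0.0, 1.0),
        neurite_channel=None if neurite is None else np.clip(neurite, 0.0, 1.0),
        scale=scale,
        source_path=str(path),
        bit_depth=bit_depth,
    )


def _image_files(directory: Path) -> list[Path]:
    return sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def discover_dataset(root: str | Path) -> DatasetLayout:
    """Find the nested-folder layout under ``root``.

    A root that directly contains images is a single round named after the
    root folder; otherwise each subdirectory is one round (condition), sorted
    lexicographically so round order is deterministic. Subfolders without any
    recognized image are dropped with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise InputError(f"dataset root is not a directory: {root}")
    direct = _image_files(root)
    if direct:
        return DatasetLayout(rounds=[(root.name, direct)])
    rounds: list[tuple[str, list[Path]]] = []
    for sub in sorted((p for p in root.iterdir() if p.is_dir()), key=lambda p: p.name):
        files = _image_files(sub)
        if files:
            rounds.append((sub.name, files))
        else:
            logger.warning("round folder %s contains no images; dropped", sub)
    if not rounds:
        raise EmptyDatasetError(f"no images found under {root}")
    return DatasetLayout(rounds=rounds)
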