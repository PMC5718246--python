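"""Synthetic fluorescence fields with known ground truth.

Emulates two-channel confocal fields of cultured neurons: the puncta channel
is a sum of isotropic Gaussian spots (protein puncta are typically 0.4-4 um
across) over a flat background with additive Gaussian noise (optionally
Poisson shot noise); the neurite channel holds smooth random-walk dendrite
ribbons and disk-shaped somata. Every punctum's center, width and peak are
recorded so detections can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigError
from .image_io import MultiChannelImage, PixelScale

DEFAULT_SCALE = PixelScale(101.6 / 1024, 101.6 / 1024)  # ~0.0992 um/px


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one simulated field.

    Defaults mimic a healthy mid-development culture imaged at ~0.1 um/px:
    a few dendrite ribbons ~1 um wide crossing the field, most puncta within
    the correlation margin of a ribbon, puncta sigma 2-5 px (footprint
    diameters ~0.8-2 um), peaks well above the lowest threshold, and
    background plus noise giving an SNR of roughly 10.
    """

    shape_px: tuple[int, int] = (256, 256)
    scale: PixelScale = DEFAULT_SCALE
    n_puncta: int = 30
    sigma_range_px: tuple[float, float] = (2.0, 5.0)
    peak_range: tuple[float, float] = (0.6, 0.95)
    dendrite_count: int = 3
    ribbon_width_um: float = 1.0
    soma_count: int = 1
    soma_diameter_um: float = 12.0
    fraction_of_puncta_on_dendrites: float = 0.85
    background_level: float = 0.02
    gaussian_noise_sd: float = 0.06
    poisson_noise: bool = False
    merged_pair_fraction: float = 0.0
    min_separation_px: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape_px) < 16:
            raise ConfigError("field must be at least 16 px on a side")
        for lo, hi in (self.sigma_range_px, self.peak_range):
            if lo > hi:
                raise ConfigError("ranges must be ordered (lo <= hi)")
        for f in (self.fraction_of_puncta_on_dendrites, self.merged_pair_fraction):
            if not 0.0 <= f <= 1.0:
                raise ConfigError("fractions must lie in [0,1]")
        if self.n_puncta < 0 or self.dendrite_count < 0 or self.soma_count < 0:
            raise ConfigError("counts must be non-negative")


@dataclass
class GroundTruth:
    """True puncta parameters and structure masks of one simulated field."""

    puncta: list[tuple[tuple[float, float], float, float, bool]] = field(default_factory=list)
    dendrite_mask: np.ndarray | None = None
    soma_mask: np.ndarray | None = None

    def centers_px(self) -> np.ndarray:
        return np.array([c for c, _, _, _ in self.puncta], dtype=np.float64).reshape(-1, 2)

    def footprint_area_um2(self, scale: PixelScale) -> np.ndarray:
        """True footprint of each punctum: the disk of radius 2*sigma (a
        Gaussian spot is visually bounded at about two widths)."""
        sig = np.array([s for _, s, _, _ in self.puncta])
        return math.pi * (2 * sig) ** 2 * scale.pixel_area_um2


def _draw_ribbons(shape, rng, count, width_px) -> np.ndarray:
    """Smooth random-walk ribbons: a heading random walk drawn with a round
    brush of the ribbon half-width."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.ogrid[:h, :w]
    half = max(1.0, width_px / 2)
    for _ in range(count):
        r = rng.uniform(0.1 * h, 0.9 * h)
        c = 0.0
        theta = rng.uniform(-0.35, 0.35)
        pts = []
        while 0 <= r < h and c < w:
            pts.append((r, c))
            theta += rng.normal(0, 0.08)
            theta = float(np.clip(theta, -1.0, 1.0))
            r += 2.0 * math.sin(theta)
            c += 2.0 * math.cos(theta)
        for pr, pc in pts[:: max(1, int(half))]:
            mask |= (yy - pr) ** 2 + (xx - pc) ** 2 <= half**2
    return mask


def _add_gaussian(img: np.ndarray, center, sigma: float, peak: float) -> None:
    h, w = img.shape
    r0, c0 = center
    ext = int(math.ceil(4 * sigma))
    r_lo, r_hi = max(0, int(r0) - ext), min(h, int(r0) + ext + 1)
    c_lo, c_hi = max(0, int(c0) - ext), min(w, int(c0) + ext + 1)
    yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    img[r_lo:r_hi, c_lo:c_hi] += peak * np.exp(
        -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma**2)
    )


def generate_field(spec: FieldSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one two-channel field and its ground truth, reproducibly from
    ``spec.seed``.

    Puncta centers keep ``min_separation_px`` between singletons; a
    ``merged_pair_fraction`` of the puncta are instead placed as close pairs
    (centers under two widths apart) that fuse at the lowest threshold, to
    exercise watershed splitting. Raises a packing error when the requested
    count cannot fit in the field.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    px_um = spec.scale.microns_per_pixel_x

    dendrites = _draw_ribbons(
        (h, w), rng, spec.dendrite_count, spec.ribbon_width_um / px_um
    )
    soma_mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.ogrid[:h, :w]
    for _ in range(spec.soma_count):
        rad = spec.soma_diameter_um / px_um / 2
        if 2 * rad >= min(h, w):
            raise ConfigError("soma does not fit: enlarge the field or shrink the soma")
        r0 = rng.uniform(rad, h - rad)
        c0 = rng.uniform(rad, w - rad)
        soma_mask |= (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2

    dendrite_coords = np.argwhere(dendrites)

    n_pairs = int(round(spec.n_puncta * spec.merged_pair_fraction / 2))
    n_single = spec.n_puncta - 2 * n_pairs
    margin = 4 * spec.sigma_range_px[1]
    placed: list[tuple[float, float]] = []
    puncta: list[tuple[tuple[float, float], float, float, bool]] = []

    def try_sample(on_dendrite: bool, attempts: int) -> tuple[float, float] | None:
        for _ in range(attempts):
            if on_dendrite and len(dendrite_coords):
                r, c = dendrite_coords[rng.integers(len(dendrite_coords))]
                r = float(r) + rng.normal(0, 2)
                c = float(c) + rng.normal(0, 2)
            else:
                r = rng.uniform(margin, h - margin)
                c = rng.uniform(margin, w - margin)
            if not (margin <= r <= h - margin and margin <= c <= w - margin):
                continue
            if all((r - pr) ** 2 + (c - pc) ** 2 >= spec.min_separation_px**2
                   for pr, pc in placed):
                return r, c
        return None

    def sample_center(on_dendrite: bool) -> tuple[tuple[float, float], bool]:
        """Returns (center, actually_on_dendrite); falls back to off-dendrite
        placement when the ribbons within the field margin are saturated."""
        pos = try_sample(on_dendrite, 2000)
        if pos is not None:
            return pos, on_dendrite
        if on_dendrite:
            pos = try_sample(False, 2000)
            if pos is not None:
                return pos, False
        raise ConfigError("could not place puncta: field too crowded for the requested layout")

    def new_punctum(center, on_dendrite):
        sigma = float(rng.uniform(*spec.sigma_range_px))
        peak = float(rng.uniform(*spec.peak_range))
        placed.append(center)
        puncta.append((center, sigma, peak, on_dendrite))

    for _ in range(n_single):
        want_d = bool(rng.random() < spec.fraction_of_puncta_on_dendrites) and dendrites.any()
        center, on_d = sample_center(want_d)
        new_punctum(center, on_d)
    for _ in range(n_pairs):
        want_d = bool(rng.random() < spec.fraction_of_puncta_on_dendrites) and dendrites.any()
        (r, c), on_d = sample_center(want_d)
        sigma = float(rng.uniform(*spec.sigma_range_px))
        peaks = [float(rng.uniform(*spec.peak_range)) for _ in range(2)]
        # Place members so their lowest-threshold (30/255) footprints fuse
        # while their second-threshold (70/255) cores stay separate. The
        # saddle between two equal-width Gaussians at separation d carries
        # intensity (p1+p2)*exp(-d^2/(8 sigma^2)), so fusion at threshold t
        # happens for d < sigma*sqrt(8 ln((p1+p2)/t)); aim at the geometric
        # midpoint of the two threshold bands.
        s_peaks = sum(peaks)
        t_mid = math.sqrt((30 / 255) * (70 / 255))
        sep = max(2.2 * sigma, sigma * math.sqrt(8 * math.log(max(s_peaks / t_mid, 1.5))))
        ang = rng.uniform(0, 2 * math.pi)
        for s, peak in zip((-0.5, 0.5), peaks):
            center = (r + s * sep * math.sin(ang), c + s * sep * math.cos(ang))
            placed.append(center)
            puncta.append((center, sigma, peak, on_d))

    puncta_ch = np.full((h, w), spec.background_level, dtype=np.float64)
    for center, sigma, peak, _ in puncta:
        _add_gaussian(puncta_ch, center, sigma, peak)

    neurite_ch = np.full((h, w), spec.background_level, dtype=np.float64)
    neurite_ch[dendrites] += 0.55
    neurite_ch[soma_mask] += 0.45
    neurite_ch *= 1 + 0.08 * rng.standard_normal((h, w)) * (dendrites | soma_mask)

    for ch in (puncta_ch, neurite_ch):
        if spec.poisson_noise:
            photons = 200.0
            ch[:] = rng.poisson(np.clip(ch, 0, None) * photons) / photons
        if spec.gaussian_noise_sd > 0:
            ch += rng.normal(0, spec.gaussian_noise_sd, size=ch.shape)
        np.clip(ch, 0.0, 1.0, out=ch)

    image = MultiChannelImage(
        puncta_channel=puncta_ch,
        neurite_channel=neurite_ch,
        scale=spec.scale,
        source_path=f"synthetic(seed={spec.seed})",
        bit_depth=8,
    )
    truth = GroundTruth(puncta=puncta, dendrite_mask=dendrites, soma_mask=soma_mask)
    return image, truth


def write_field_tiff(image: MultiChannelImage, path, bit_depth: int = 8) -> None:
    """Write a generated field as an RGB TIFF (red = puncta, green = neurite),
    to exercise the file-reading path end to end."""
    full = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    h, w = image.puncta_channel.shape
    rgb = np.zeros((h, w, 3), dtype=dtype)
    rgb[..., 0] = np.round(image.puncta_channel * full).astype(dtype)
    if image.neurite_channel is not None:
        rgb[..., 1] = np.round(image.neurite_channel * full).astype(dtype)
    tifffile.imwrite(path, rgb, photometric="rgb")


def score_detection(
    truth: GroundTruth,
    detected,
    scale: PixelScale,
    match_radius_um: float = 0.5,
) -> dict:
    """Greedy one-to-one nearest-centroid matching of detections to truth.

    Returns recall, precision (None when there are no detections), and the
    per-match relative area errors against the true 2-sigma disk footprint.
    """
    true_centers = truth.centers_px()
    true_um = np.column_stack(
        [true_centers[:, 1] * scale.microns_per_pixel_x,
         true_centers[:, 0] * scale.microns_per_pixel_y]
    ) if len(true_centers) else np.zeros((0, 2))
    det_um = np.array([r.centroid_um for r in detected], dtype=np.float64).reshape(-1, 2)
    true_areas = truth.footprint_area_um2(scale)

    pairs = []
    for i in range(len(true_um)):
        for j in range(len(det_um)):
            d = float(np.hypot(*(true_um[i] - det_um[j])))
            if d <= match_radius_um:
                pairs.append((d, i, j))
    pairs.sort()
    used_t, used_d, matches = set(), set(), []
    for d, i, j in pairs:
        if i not in used_t and j not in used_d:
            used_t.add(i)
            used_d.add(j)
            matches.append((i, j))
    recall = len(matches) / len(true_um) if len(true_um) else 1.0
    precision = len(matches) / len(det_um) if len(det_um) else None
    area_errors = [
        (detected[j].area_um2 - true_areas[i]) / true_areas[i] for i, j in matches
    ]
    return {
        "recall": recall,
        "precision": precision,
        "n_matched": len(matches),
        "area_errors": area_errors,
        "mean_abs_area_error": float(np.mean(np.abs(area_errors))) if area_errors else None,
    }


__all__ = [
    "FieldSpec", "GroundTruth", "generate_field", "write_field_tiff", "score_detection",
]
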