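"""Quantitative H&E slide analysis.

Turns a digitized hematoxylin-and-eosin slide into per-pixel stain labels and
voxelized epithelium / stroma / adipose volume-fraction maps:

1. white balance against a bright background reference,
2. optical-density color deconvolution onto a 3-stain absorbance basis,
3. HSV-saturation comparison of the re-rendered single-stain images to label
   each pixel hematoxylin / eosin / no-stain,
4. label counting within square voxels (default 200 um) to produce fractions.

Epithelium is identified with hematoxylin-labeled pixels, stroma with eosin,
and adipose with unstained white space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "StainLabel",
    "SlideImage",
    "StainChannels",
    "BinaryStainMap",
    "FractionMap",
    "RoiMask",
    "default_stain_vectors",
    "white_balance",
    "color_deconvolve",
    "binarize_stains",
    "compute_fractions",
    "roi_statistics",
]

#: Standard H&E RGB absorbance directions (unnormalized).
HEMATOXYLIN_ABSORBANCE = (0.650, 0.704, 0.286)
EOSIN_ABSORBANCE = (0.072, 0.990, 0.105)


class StainLabel(enum.IntEnum):
    """Per-pixel stain class."""

    NO_STAIN = 0
    HEMATOXYLIN = 1
    EOSIN = 2


def default_stain_vectors() -> np.ndarray:
    """Return the default 3x3 stain basis, one unit row per stain.

    Rows are (hematoxylin, eosin, residual); the residual direction is the
    normalized cross product of the first two.
    """
    h = np.asarray(HEMATOXYLIN_ABSORBANCE, dtype=float)
    e = np.asarray(EOSIN_ABSORBANCE, dtype=float)
    h = h / np.linalg.norm(h)
    e = e / np.linalg.norm(e)
    r = np.cross(h, e)
    r = r / np.linalg.norm(r)
    return np.stack([h, e, r])


@dataclass
class SlideImage:
    """8-bit RGB digitized slide with its scan resolution in pixels per mm."""

    pixels: np.ndarray
    resolution: float
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StainChannels:
    """Per-pixel stain optical densities on a 3-stain absorbance basis."""

    hematoxylin_od: np.ndarray
    eosin_od: np.ndarray
    residual_od: np.ndarray
    stain_vectors: np.ndarray


@dataclass
class BinaryStainMap:
    """Per-pixel partition into hematoxylin / eosin / no-stain labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = np.isin(self.labels, [int(v) for v in StainLabel])
        if not valid.all():
            raise ValueError("labels must be one of StainLabel values")


@dataclass
class FractionMap:
    """Voxelized epithelium/stroma/adipose volume fractions.

    Per voxel the three fractions are pixel-count ratios and sum to 1 exactly.
    """

    epithelium: np.ndarray
    stroma: np.ndarray
    adipose: np.ndarray
    voxel_size: float = 200.0
    pixels_per_voxel: int = 0

    def __post_init__(self) -> None:
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.epithelium.shape

    def stack(self) -> np.ndarray:
        """(rows, cols, 3) float32 array ordered epithelium, stroma, adipose."""
        return np.stack(
            [self.epithelium, self.stroma, self.adipose], axis=-1
        ).astype(np.float32)


@dataclass
class RoiMask:
    """Boolean region-of-interest mask aligned to its parent map."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one true pixel")


def white_balance(image: SlideImage, percentile: float = 99.0) -> SlideImage:
    """Rescale each channel so its bright background reference maps to 255.

    The reference is the per-channel ``percentile`` intensity (default 99th);
    output values are clipped to [0, 255].
    """
    pixels = image.pixels.astype(float)
    ref = np.percentile(pixels.reshape(-1, 3), percentile, axis=0)
    if np.any(ref <= 0):
        raise ValueError("no white reference: a channel's reference intensity is 0")
    balanced = np.clip(np.rint(pixels * (255.0 / ref)), 0, 255).astype(np.uint8)
    return SlideImage(balanced, image.resolution, image.specimen_id)


def _optical_density(pixels: np.ndarray) -> np.ndarray:
    # intensity floored at 1 so OD stays finite
    return -np.log10(np.maximum(pixels.astype(float), 1.0) / 255.0)


def color_deconvolve(
    image: SlideImage, stain_vectors: np.ndarray | None = None
) -> StainChannels:
    """Unmix an RGB slide into stain optical densities.

    Per pixel, OD = -log10(max(I, 1)/255) per channel; the three stain ODs
    solve the 3x3 linear system projecting pixel OD onto the stain basis.
    Negative solutions are clipped to 0.
    """
    vectors = (
        default_stain_vectors() if stain_vectors is None else np.asarray(stain_vectors, float)
    )
    if vectors.shape != (3, 3):
        raise ValueError("stain_vectors must be a 3x3 matrix (one stain per row)")
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0) or abs(np.linalg.det(vectors)) < 1e-10:
        raise ValueError("degenerate stain basis")
    vectors = vectors / norms[:, None]

    od = _optical_density(image.pixels)
    # od_pixel = d @ vectors  =>  d = od @ vectors^{-1}
    densities = od.reshape(-1, 3) @ np.linalg.inv(vectors)
    densities = np.clip(densities, 0.0, None).reshape(image.pixels.shape)
    return StainChannels(
        hematoxylin_od=densities[..., 0],
        eosin_od=densities[..., 1],
        residual_od=densities[..., 2],
        stain_vectors=vectors,
    )


def render_stain(od: np.ndarray, stain_vector: np.ndarray) -> np.ndarray:
    """Re-render one stain's OD channel as its single-stain RGB image in [0, 1]."""
    return 10.0 ** (-np.asarray(od)[..., None] * np.asarray(stain_vector))


def stain_saturation(od: np.ndarray, stain_vector: np.ndarray) -> np.ndarray:
    """HSV saturation of the single-stain rendering of one OD channel."""
    return rgb2hsv(render_stain(od, stain_vector))[..., 1]


def binarize_stains(
    channels: StainChannels,
    sat_threshold_fraction: float = 0.1,
    per_image_max: bool = False,
) -> BinaryStainMap:
    """Label each pixel hematoxylin, eosin, or no-stain by HSV saturation.

    Each stain channel is rendered as its single-stain RGB image and converted
    to HSV. Pixels whose two stain saturations both fall below
    ``sat_threshold_fraction`` times the reference saturation (1.0, or the
    image maximum when ``per_image_max``) are white space (no stain); otherwise
    the larger saturation wins, with exact ties labeled no-stain.
    """
    if not 0 < sat_threshold_fraction < 1:
        raise ValueError("sat_threshold_fraction must be in (0, 1)")
    sat_h = stain_saturation(channels.hematoxylin_od, channels.stain_vectors[0])
    sat_e = stain_saturation(channels.eosin_od, channels.stain_vectors[1])
    reference = max(sat_h.max(), sat_e.max()) if per_image_max else 1.0
    threshold = sat_threshold_fraction * reference

    labels = np.full(sat_h.shape, int(StainLabel.NO_STAIN), dtype=np.int8)
    significant = ~((sat_h < threshold) & (sat_e < threshold))
    labels[significant & (sat_h > sat_e)] = int(StainLabel.HEMATOXYLIN)
    labels[significant & (sat_e > sat_h)] = int(StainLabel.EOSIN)
    return BinaryStainMap(labels)


def _block_sums(mask: np.ndarray, side: int) -> np.ndarray:
    rows = np.arange(0, mask.shape[0], side)
    cols = np.arange(0, mask.shape[1], side)
    summed = np.add.reduceat(mask.astype(np.int64), rows, axis=0)
    return np.add.reduceat(summed, cols, axis=1)


def compute_fractions(
    labels: BinaryStainMap, resolution: float, voxel_size: float = 200.0
) -> FractionMap:
    """Count stain labels within square voxels to get volume fractions.

    The image is tiled from the top-left into voxels of side
    ``round(voxel_size * resolution / 1000)`` pixels; edge voxels use the
    available pixels. Per voxel, epithelium = hematoxylin count / total,
    stroma = eosin count / total, adipose = no-stain count / total.
    """
    grid = labels.labels
    if grid.size == 0:
        raise ValueError("empty label map")
    side = int(round(voxel_size * resolution / 1000.0))
    if side < 1:
        raise ValueError("voxel smaller than one pixel at this resolution")

    counts = {
        lab: _block_sums(grid == int(lab), side)
        for lab in (StainLabel.HEMATOXYLIN, StainLabel.EOSIN, StainLabel.NO_STAIN)
    }
    total = _block_sums(np.ones_like(grid, dtype=bool), side)
    return FractionMap(
        epithelium=counts[StainLabel.HEMATOXYLIN] / total,
        stroma=counts[StainLabel.EOSIN] / total,
        adipose=counts[StainLabel.NO_STAIN] / total,
        voxel_size=voxel_size,
        pixels_per_voxel=side,
    )


def _named_quantities(map_like) -> tuple[Mapping[str, np.ndarray], np.ndarray | None]:
    if isinstance(map_like, FractionMap):
        return (
            {
                "epithelium": map_like.epithelium,
                "stroma": map_like.stroma,
                "adipose": map_like.adipose,
            },
            None,
        )
    if hasattr(map_like, "mus_prime"):  # OpticalPropertyMap (duck-typed)
        valid = getattr(map_like, "valid_mask", None)
        return (
            {
                "mus_prime": map_like.mus_prime,
                "gamma": map_like.gamma,
                "b_power": map_like.b_power,
            },
            valid,
        )
    raise TypeError("expected a FractionMap or an OpticalPropertyMap")


def roi_statistics(map_like, roi: RoiMask) -> dict[str, tuple[float, float, int]]:
    """Sample mean and standard deviation (n-1 denominator) within an ROI.

    Returns ``{quantity: (mean, std, n)}`` over in-mask, in-validity pixels.
    ``std`` is NaN when only one pixel is in the intersection.
    """
    quantities, valid = _named_quantities(map_like)
    some = next(iter(quantities.values()))
    if roi.mask.shape != some.shape:
        raise ValueError("ROI mask is not aligned to the map grid")
    select = roi.mask if valid is None else (roi.mask & valid)
    if not select.any():
        raise ValueError("empty ROI")

    out: dict[str, tuple[float, float, int]] = {}
    n = int(select.sum())
    for name, values in quantities.items():
        sample = values[select].astype(float)
        std = float(np.std(sample, ddof=1)) if n > 1 else float("nan")
        out[name] = (float(sample.mean()), std, n)
    return out
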