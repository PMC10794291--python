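"""Picrosirius-red (PSR) polarized-light collagen hue quantification.

Under circularly polarized light, PSR-stained collagen is birefringent
with a hue that roughly tracks fiber thickness: red fibers are the
thickest, then orange, yellow, and green the thinnest.  The pipeline
decomposes an RGB micrograph into 8-bit hue/saturation/intensity
channels, discards dim or washed-out pixels and the blue/purple hue band
that is neither background nor collagen, classifies the surviving pixels
into the four thickness bands, and converts the classified hues into a
single monotone "height" scale (normalized to the strongest red observed
within an experiment) that feeds the local fractal surface analysis.

8-bit hue bands:  red 0-9 and 230-255 (wraparound), orange 10-38,
yellow 39-51, green 52-128; hues 129-229 are disregarded.  Pixels with
saturation <= 142 or intensity <= 15 are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from skimage import color

from .core import HeightImage

__all__ = [
    "HueClass",
    "HUE_RANGES",
    "SATURATION_MIN",
    "INTENSITY_MIN",
    "DISREGARDED_HUE",
    "RgbImage",
    "HsiImage",
    "HueClassImage",
    "CollagenStats",
    "AnimalStats",
    "rgb_to_hsi8",
    "classify_hue",
    "apply_psr_thresholds",
    "unwrap_hue",
    "hue_to_thickness_rank",
    "normalize_hue_to_height",
    "collagen_area_fraction",
    "class_counts",
    "aggregate_animal",
]


class HueClass(enum.IntEnum):
    """Collagen fiber-thickness classes, plus background (non-collagen)."""

    BACKGROUND = 0
    RED = 1      # thickest fibers
    ORANGE = 2
    YELLOW = 3
    GREEN = 4    # thinnest fibers


# Inclusive 8-bit hue ranges per class; red wraps around 255 -> 0.
HUE_RANGES: dict[HueClass, tuple[tuple[int, int], ...]] = {
    HueClass.RED: ((0, 9), (230, 255)),
    HueClass.ORANGE: ((10, 38),),
    HueClass.YELLOW: ((39, 51),),
    HueClass.GREEN: ((52, 128),),
}
SATURATION_MIN = 143  # saturation 0-142 excluded
INTENSITY_MIN = 16    # intensity 0-15 excluded
DISREGARDED_HUE = (129, 229)  # neither background nor collagen


@dataclass
class RgbImage:
    """8-bit RGB micrograph with physical pixel size in micrometers."""

    values: np.ndarray  # (H, W, 3) uint8
    pixel_size: float = 0.369

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != 3 or v.dtype != np.uint8:
            raise ValueError("RGB image must be (H, W, 3) uint8")
        self.values = v


@dataclass
class HsiImage:
    """8-bit hue, saturation and intensity channels on a shared grid."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray
    pixel_size: float = 0.369


@dataclass
class HueClassImage:
    """Per-pixel thickness class plus the raw 8-bit hue it came from."""

    classes: np.ndarray  # uint8 of HueClass codes
    raw_hue: np.ndarray  # uint8
    pixel_size: float = 0.369

    @property
    def collagen_mask(self) -> np.ndarray:
        return self.classes != int(HueClass.BACKGROUND)


@dataclass
class CollagenStats:
    """Per-image collagen bookkeeping."""

    area_fraction: float
    counts: dict[str, int]
    tissue_pixel_count: int


@dataclass
class AnimalStats:
    """Mean and sample SD of area fractions over one animal's images."""

    mean: float
    sd: float
    n: int
    sd_defined: bool


def rgb_to_hsi8(img: RgbImage | np.ndarray) -> HsiImage:
    """Decompose 8-bit RGB into 8-bit hue/saturation/intensity channels.

    Uses the hexagonal hue transform (hue 0 at red, wrapping at 255);
    each channel is scaled to 0-255 and rounded to the nearest integer.
    Achromatic pixels get hue 0.
    """
    if isinstance(img, RgbImage):
        values, px = img.values, img.pixel_size
    else:
        values, px = RgbImage(np.asarray(img)).values, 0.369
    hsv = color.rgb2hsv(values)
    as8 = lambda ch: np.round(ch * 255.0).astype(np.uint8)
    return HsiImage(hue=as8(hsv[..., 0]), saturation=as8(hsv[..., 1]),
                    intensity=as8(hsv[..., 2]), pixel_size=px)


def classify_hue(h: int | np.ndarray) -> int | np.ndarray:
    """Map 8-bit hue(s) to a thickness class code.

    Scalar input in the disregarded band 129-229 raises; array input maps
    that band to BACKGROUND (callers apply the thresholds first).
    """
    scalar = np.isscalar(h)
    arr = np.atleast_1d(np.asarray(h, dtype=np.int64))
    if scalar and DISREGARDED_HUE[0] <= arr[0] <= DISREGARDED_HUE[1]:
        raise ValueError(f"hue {int(arr[0])} lies in the disregarded band "
                         f"{DISREGARDED_HUE[0]}-{DISREGARDED_HUE[1]}")
    out = np.full(arr.shape, int(HueClass.BACKGROUND), dtype=np.uint8)
    for cls, ranges in HUE_RANGES.items():
        for lo, hi in ranges:
            out[(arr >= lo) & (arr <= hi)] = int(cls)
    return int(out[0]) if scalar else out.reshape(np.shape(h))


def apply_psr_thresholds(hsi: HsiImage) -> HueClassImage:
    """Retain pixels passing the saturation/intensity/hue cuts and classify.

    A pixel survives iff saturation >= 143, intensity >= 16 and its hue is
    outside 129-229; survivors are classified by the hue band table and
    everything else becomes background.  Idempotent by construction.
    """
    keep = (
        (hsi.saturation >= SATURATION_MIN)
        & (hsi.intensity >= INTENSITY_MIN)
        & ~((hsi.hue >= DISREGARDED_HUE[0]) & (hsi.hue <= DISREGARDED_HUE[1]))
    )
    classes = np.where(keep, classify_hue(hsi.hue), np.uint8(HueClass.BACKGROUND))
    return HueClassImage(classes=classes.astype(np.uint8),
                         raw_hue=hsi.hue.copy(), pixel_size=hsi.pixel_size)


def unwrap_hue(h: np.ndarray) -> np.ndarray:
    """Unwrap the red wraparound: hues 230-255 become -26..-1."""
    h = np.asarray(h, dtype=np.int64)
    return np.where(h >= 230, h - 256, h)


def hue_to_thickness_rank(h: np.ndarray) -> np.ndarray:
    """Integer rank increasing with fiber thickness: 128 - unwrapped hue.

    Green 52-128 maps to 0..76, yellow to 77..89, orange to 90..118, and
    red (wrapped) to 119..154, so thicker fibers always rank higher.
    """
    return 128 - unwrap_hue(h)


def normalize_hue_to_height(
    images: list[HueClassImage], experiment_id: str | None = None
) -> list[HeightImage]:
    """Convert classified hues into height images on a shared (0, 1] scale.

    Retained hues are ranked by thickness (``hue_to_thickness_rank``),
    offset by +1 so the greenest retained hue stays strictly positive, and
    divided by the experiment-wide maximum offset rank — attained at the
    strongest red hue observed in the experiment, which therefore maps to
    exactly 1.  Background pixels map to 0.
    """
    ranks = []
    rank_max = 0
    any_retained = False
    for img in images:
        m = img.collagen_mask
        r = np.zeros(img.classes.shape, dtype=np.int64)
        if m.any():
            any_retained = True
            r[m] = hue_to_thickness_rank(img.raw_hue[m]) + 1
            rank_max = max(rank_max, int(r.max()))
        ranks.append(r)
    if not any_retained:
        raise ValueError(f"experiment {experiment_id!r} has no retained pixels")
    return [HeightImage(r / rank_max, pixel_size=img.pixel_size)
            for r, img in zip(ranks, images)]


def collagen_area_fraction(img: HueClassImage, tissue_pixel_count: int | None = None) -> float:
    """Collagen pixels over tissue pixels (default: all pixels of the image)."""
    n_coll = int(img.collagen_mask.sum())
    if tissue_pixel_count is None:
        tissue_pixel_count = img.classes.size
    if tissue_pixel_count == 0:
        raise ValueError("tissue_pixel_count must be positive")
    if tissue_pixel_count < n_coll:
        raise ValueError("tissue_pixel_count is smaller than the collagen pixel count")
    return n_coll / tissue_pixel_count


def class_counts(img: HueClassImage) -> dict[str, int]:
    """Pixel count per thickness class (background excluded)."""
    return {cls.name.lower(): int((img.classes == int(cls)).sum())
            for cls in HueClass if cls != HueClass.BACKGROUND}


def collagen_stats(img: HueClassImage, tissue_pixel_count: int | None = None) -> CollagenStats:
    counts = class_counts(img)
    n_tissue = tissue_pixel_count if tissue_pixel_count is not None else img.classes.size
    return CollagenStats(
        area_fraction=collagen_area_fraction(img, tissue_pixel_count),
        counts=counts, tissue_pixel_count=n_tissue,
    )


def aggregate_animal(fractions: list[float]) -> AnimalStats:
    """Mean and sample SD (n-1) of an animal's per-image area fractions.

    A single image yields SD 0 with ``sd_defined=False``.
    """
    arr = np.asarray(fractions, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("need at least one area fraction")
    if arr.size == 1:
        return AnimalStats(mean=float(arr[0]), sd=0.0, n=1, sd_defined=False)
    return AnimalStats(mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                       n=int(arr.size), sd_defined=True)
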