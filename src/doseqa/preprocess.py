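"""Comparison-image preprocessing: field crop, normalization, square resize.

The pipeline mirrors standard practice for feeding dose-comparison images
to a conv-net: crop to the radiation field (bounding box of the reference
dose above a 10% low-dose threshold), normalize with statistics pooled over
the *training* images only, and resample each channel to a square side of
32, 64 or 128 pixels.  Because the crop box tracks the field, the physical
pixel size of the square images depends on modality and field size; see
:func:`report_pixel_pitch` for the resulting arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import math

import numpy as np
from skimage.transform import resize as _sk_resize

from .compare import ComparisonImage
from .plans import DoseImage

__all__ = [
    "Normalization",
    "PreprocessConfig",
    "DatasetStats",
    "crop_to_field",
    "field_bounding_box",
    "compute_dataset_stats",
    "normalize",
    "resize_square",
    "report_pixel_pitch",
    "preprocess_image",
]

VALID_SIDES = (32, 64, 128)

def _chw(a) -> np.ndarray:
    """Coerce to a channel-first (c, h, w) float array."""
    a = np.asarray(a, dtype=float)
    return a[None] if a.ndim == 2 else a



class Normalization(str, Enum):
    MINMAX = "minmax"
    MEANSTD = "meanstd"


@dataclass
class PreprocessConfig:
    crop_threshold_fraction: float = 0.10
    normalization: Normalization = Normalization.MEANSTD
    target_side_px: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_threshold_fraction < 1.0:
            raise ValueError("crop threshold must be a fraction in (0, 1)")
        self.normalization = Normalization(self.normalization)
        if self.target_side_px not in VALID_SIDES:
            raise ValueError(f"target side must be one of {VALID_SIDES}")


@dataclass
class DatasetStats:
    """Per-channel pooled pixel statistics of a training split.

    Clip bounds for min/max normalization are mean ± 2·stdev.
    """

    mean: np.ndarray
    stdev: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.stdev = np.atleast_1d(np.asarray(self.stdev, dtype=float))
        if self.mean.shape != self.stdev.shape:
            raise ValueError("mean and stdev must have one value per channel")
        if np.any(self.stdev <= 0):
            raise ValueError("stdev must be positive (zero-variance dataset)")

    @property
    def clip_min(self) -> np.ndarray:
        return self.mean - 2.0 * self.stdev

    @property
    def clip_max(self) -> np.ndarray:
        return self.mean + 2.0 * self.stdev


def field_bounding_box(
    ref: DoseImage | np.ndarray, threshold: float = 0.10
) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) half-open bounding box of the radiation field.

    The field is the set of pixels where the reference dose is at or above
    ``threshold × max(ref)``.
    """
    R = ref.pixels if isinstance(ref, DoseImage) else np.asarray(ref, dtype=float)
    if R.max() <= 0:
        raise ValueError("empty field mask: reference dose has no positive pixels")
    mask = R >= threshold * R.max()
    if not mask.any():  # pragma: no cover - max pixel always passes
        raise ValueError("empty field mask: no pixel reaches the crop threshold")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def crop_to_field(
    comp: ComparisonImage,
    ref: DoseImage,
    threshold: float = 0.10,
) -> ComparisonImage:
    """Crop all channels to the reference-dose field bounding box.

    The crop mask is defined on the error-free reference dose — the
    radiation field is a dose concept, and comparison images can be signed
    or neutral-valued outside the field.
    """
    if comp.shape != ref.shape:
        raise ValueError("comparison image and reference dose must share a grid")
    r0, r1, c0, c1 = field_bounding_box(ref, threshold)
    out = ComparisonImage(
        comp.channels[:, r0:r1, c0:c1].copy(),
        comp.method,
        list(comp.channel_names),
        comp.pixel_pitch_mm,
        meta=dict(comp.meta),
    )
    out.meta["crop_box"] = (r0, r1, c0, c1)
    out.meta["crop_threshold"] = threshold
    return out


def compute_dataset_stats(images: Sequence[ComparisonImage | np.ndarray]) -> DatasetStats:
    """Per-channel mean/stdev pooled over all pixels of all images.

    Accepts images of differing spatial shape (e.g. per-plan crop boxes).
    Population stdev.  Must only ever be fed the training split.
    """
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least two images for dataset statistics")
    arrays = [
        im.channels if isinstance(im, ComparisonImage) else _chw(im)
        for im in images
    ]
    n_ch = arrays[0].shape[0]
    if any(a.shape[0] != n_ch for a in arrays):
        raise ValueError("all images must have the same channel count")
    n = np.zeros(n_ch)
    s1 = np.zeros(n_ch)
    s2 = np.zeros(n_ch)
    for a in arrays:
        n += a[0].size
        s1 += a.sum(axis=(1, 2))
        s2 += (a * a).sum(axis=(1, 2))
    mean = s1 / n
    var = s2 / n - mean**2
    var = np.maximum(var, 0.0)
    if np.any(var == 0):
        raise ValueError("zero-variance channel in dataset")
    return DatasetStats(mean, np.sqrt(var))


def normalize(
    img: ComparisonImage | np.ndarray,
    stats: DatasetStats,
    mode: Normalization | str,
) -> np.ndarray:
    """Normalize a (c, h, w) image with dataset statistics.

    MINMAX clips each channel to mean ± 2·stdev and maps that range to
    [0, 1]; MEANSTD standardizes to (x − mean)/stdev, unbounded.
    """
    mode = Normalization(mode)
    a = img.channels if isinstance(img, ComparisonImage) else _chw(img)
    mean = stats.mean[:, None, None]
    std = stats.stdev[:, None, None]
    if mode is Normalization.MEANSTD:
        return (a - mean) / std
    lo = stats.clip_min[:, None, None]
    hi = stats.clip_max[:, None, None]
    return (np.clip(a, lo, hi) - lo) / (hi - lo)


def resize_square(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinearly resample each channel of a (c, h, w) image to side × side.

    The rectangular crop is mapped directly onto the square grid, so the
    aspect ratio is not preserved; the anisotropic physical pixel pitch is
    reported separately by :func:`report_pixel_pitch`.  Bilinear sampling
    keeps every output value inside the input value range.
    """
    if side not in VALID_SIDES:
        raise ValueError(f"target side must be one of {VALID_SIDES}")
    a = _chw(img)
    if a.shape[1:] == (side, side):
        return a.copy()
    out = np.empty((a.shape[0], side, side), dtype=float)
    for c in range(a.shape[0]):
        out[c] = _sk_resize(
            a[c], (side, side), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return out


def report_pixel_pitch(cropped_px: int, original_pitch_mm: float, side: int) -> float:
    """Physical pixel size (mm) after resizing a cropped axis to ``side``.

    ``cropped_px × original_pitch_mm / side``, truncated toward zero at one
    decimal — the reporting convention used for all cropped/resized pixel
    sizes in this package.
    """
    if cropped_px <= 0 or original_pitch_mm <= 0 or side <= 0:
        raise ValueError("all arguments must be positive")
    value = cropped_px * original_pitch_mm / side
    return math.floor(round(value * 10.0, 6)) / 10.0


def preprocess_image(
    comp: ComparisonImage,
    ref: DoseImage,
    stats: DatasetStats,
    config: PreprocessConfig,
) -> np.ndarray:
    """Full crop → normalize → resize pipeline for one image.

    Note the order: the dataset statistics must themselves come from
    *cropped* training images (see :func:`compute_dataset_stats`).
    """
    cropped = crop_to_field(comp, ref, config.crop_threshold_fraction)
    normed = normalize(cropped, stats, config.normalization)
    return resize_square(normed, config.target_side_px)
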