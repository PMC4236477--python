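"""Canopy/background segmentation by G-R thresholding.

Green vegetation has a reflectance peak in the green band while soil, water
and plant residues have a nearly flat visible albedo, so the per-pixel
difference of the green and red digital numbers separates canopy from
background.  The threshold on G-R is either a fixed constant (default 0) or
chosen by Otsu's criterion on the integer G-R histogram; canopy is the
strict upper side (G - R > t).

The canopy color of an image is summarized as :class:`~ricecanopyn.color.
ChannelMeans` — the per-channel arithmetic mean over masked pixels — which
feeds the color-index computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import imageio.v3 as iio
import numpy as np
from skimage.morphology import remove_small_objects
from sklearn.base import BaseEstimator

from .color import (
    ChannelMeans,
    ColorConfig,
    ColorIndexSet,
    DEFAULT_CONFIG,
    compute_index_set,
    compute_index_set_per_pixel,
)

__all__ = [
    "CanopyImage",
    "CanopyMask",
    "CanopySegmenter",
    "SegmentationWarning",
    "gr_difference",
    "select_threshold",
    "segment_canopy",
    "canopy_channel_means",
    "image_index_set",
    "write_mask",
    "read_mask",
]


class SegmentationWarning(UserWarning):
    """Degenerate segmentation conditions (constant raster, zero coverage)."""


@dataclass
class CanopyImage:
    """An 8-bit RGB canopy photograph plus acquisition metadata.

    ``pixels`` is H x W x 3 uint8 in red/green/blue channel order, row-major
    with the origin at the top-left.  ``dat`` is days after transplanting;
    ``par`` is photosynthetic active radiation in umol m-2 s-1.
    """

    pixels: np.ndarray
    plot_id: str | None = None
    cultivar: str | None = None
    dat: int | None = None
    par: float | None = None
    acquired: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty H x W x 3 raster")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.dat is not None and self.dat < 0:
            raise ValueError("DAT must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_file(cls, path, **meta) -> "CanopyImage":
        """Load a JPEG/PNG raster; an alpha channel, if present, is dropped."""
        px = iio.imread(path)
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        if px.shape[-1] == 4:
            px = px[..., :3]
        return cls(pixels=px, **meta)


@dataclass
class CanopyMask:
    """Boolean vegetation mask with its coverage and the threshold used."""

    mask: np.ndarray
    coverage: float
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


def gr_difference(image: CanopyImage) -> np.ndarray:
    """Signed per-pixel G - R raster in [-255, 255] (int16)."""
    px = image.pixels.astype(np.int16)
    return px[:, :, 1] - px[:, :, 0]


def _integer_otsu(diff: np.ndarray) -> float:
    """Otsu threshold over integer G-R values.

    Scans every integer split of the histogram, maximizing between-class
    variance (equivalently minimizing intraclass variance); background is
    the lower class (values <= t).  Ties resolve to the smallest threshold.
    """
    vals, counts = np.unique(np.asarray(diff).ravel(), return_counts=True)
    vals = vals.astype(float)
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    s0 = np.cumsum(vals * counts)[:-1]
    mu0 = s0 / w0
    mu1 = (np.sum(vals * counts) - s0) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(vals[int(np.argmax(between))])


def select_threshold(
    diff: np.ndarray, method: str = "otsu", fixed: float = 0.0
) -> float:
    """Choose the G-R threshold.

    ``method="fixed"`` returns ``fixed`` (default 0).  ``method="otsu"``
    minimizes intraclass variance over integer thresholds of the G-R
    histogram; a constant raster falls back to ``fixed`` with a warning.
    """
    diff = np.asarray(diff)
    if diff.size == 0:
        raise ValueError("empty G-R raster")
    if method == "fixed":
        return float(fixed)
    if method == "otsu":
        if np.all(diff == diff.flat[0]):
            warnings.warn(
                "single-valued G-R raster: Otsu undefined, falling back to the "
                f"fixed threshold {fixed}",
                SegmentationWarning,
                stacklevel=2,
            )
            return float(fixed)
        return _integer_otsu(diff)
    raise ValueError(f"unknown threshold method {method!r}")


def segment_canopy(
    image: CanopyImage,
    method: str = "otsu",
    threshold: float = 0.0,
    saturation_filter: bool = False,
    min_object_size: int = 0,
) -> CanopyMask:
    """Segment canopy as pixels with G - R strictly above the threshold.

    ``saturation_filter`` additionally excludes over-exposed pixels (all
    channels >= 250, the rendered "white spot" convention).  Connected
    canopy components smaller than ``min_object_size`` pixels are removed
    when that is positive (default off: thresholding only).
    """
    diff = gr_difference(image)
    t = select_threshold(diff, method=method, fixed=threshold)
    mask = diff > t
    if saturation_filter:
        mask &= ~np.all(image.pixels >= 250, axis=-1)
    if min_object_size > 0:
        # components strictly smaller than min_object_size are dropped
        mask = remove_small_objects(mask, max_size=min_object_size - 1)
    coverage = float(mask.mean())
    if coverage == 0.0:
        warnings.warn(
            "zero canopy coverage: channel means are undefined downstream",
            SegmentationWarning,
            stacklevel=2,
        )
    return CanopyMask(mask=mask, coverage=coverage, threshold_used=float(t))


def canopy_channel_means(image: CanopyImage, mask: CanopyMask) -> ChannelMeans:
    """Per-channel arithmetic mean over masked pixels."""
    m = mask.mask
    if m.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    n = int(m.sum())
    if n == 0:
        raise ValueError("zero-coverage mask: no canopy pixels to summarize")
    sel = image.pixels[m].astype(float)
    return ChannelMeans(
        R=float(sel[:, 0].mean()),
        G=float(sel[:, 1].mean()),
        B=float(sel[:, 2].mean()),
        n_pixels=n,
    )


def image_index_set(
    image: CanopyImage,
    mask: CanopyMask,
    config: ColorConfig = DEFAULT_CONFIG,
    per_pixel: bool = False,
) -> ColorIndexSet:
    """Color indices of the masked canopy (mean-first by default)."""
    if per_pixel:
        return compute_index_set_per_pixel(
            image.pixels[mask.mask].astype(float), config
        )
    return compute_index_set(canopy_channel_means(image, mask), config)


class CanopySegmenter(BaseEstimator):
    """G-R threshold segmenter with a scikit-learn parameter surface.

    ``fit`` selects the threshold from one image's G-R histogram and stores
    it as ``threshold_``; ``segment``/``transform`` applies the fitted
    threshold (or selects per image when unfitted).

    Parameters
    ----------
    method:
        ``"otsu"`` (default) or ``"fixed"``.
    threshold:
        The fixed threshold, and the Otsu fallback for degenerate rasters.
    saturation_filter:
        Exclude pixels with all channels >= 250 (over-exposed white spots).
    min_object_size:
        Remove canopy components smaller than this pixel count (0 = off).
    """

    def __init__(
        self,
        method: str = "otsu",
        threshold: float = 0.0,
        saturation_filter: bool = False,
        min_object_size: int = 0,
    ):
        self.method = method
        self.threshold = threshold
        self.saturation_filter = saturation_filter
        self.min_object_size = min_object_size

    def fit(self, image: CanopyImage, y=None) -> "CanopySegmenter":
        self.threshold_ = select_threshold(
            gr_difference(image), method=self.method, fixed=self.threshold
        )
        return self

    def segment(self, image: CanopyImage) -> CanopyMask:
        if hasattr(self, "threshold_"):
            return segment_canopy(
                image,
                method="fixed",
                threshold=self.threshold_,
                saturation_filter=self.saturation_filter,
                min_object_size=self.min_object_size,
            )
        return segment_canopy(
            image,
            method=self.method,
            threshold=self.threshold,
            saturation_filter=self.saturation_filter,
            min_object_size=self.min_object_size,
        )

    def transform(self, images) -> list[CanopyMask]:
        if isinstance(images, CanopyImage):
            images = [images]
        return [self.segment(img) for img in images]

    def fit_transform(self, images, y=None) -> list[CanopyMask]:
        if isinstance(images, CanopyImage):
            images = [images]
        return [self.fit(img).segment(img) for img in images]


def write_mask(mask: CanopyMask, path) -> None:
    """Write the mask as a single-channel PNG with canopy = 255."""
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255), extension=".png")


def read_mask(path) -> np.ndarray:
    """Read a 0/255 mask PNG back to boolean."""
    return np.asarray(iio.imread(path)) > 127
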