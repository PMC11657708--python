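"""Grayscale image preprocessing and class rebalancing.

Raw ultrasound frames vary in size, carry burned-in annotations at the
borders, have poor contrast, and are corrupted by multiplicative speckle
noise.  The functions here implement the standard preparation chain
(resize -> crop -> histogram equalization -> despeckle -> normalize)
plus random over/undersampling of a labeled dataset to a fixed
per-class count.

Images live in one of two declared ranges: 8-bit integer intensities
0..255 (``normalized=False``) or real values in [0, 1]
(``normalized=True``).  Histogram equalization is only defined on the
integer form; normalization converts to the real form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "GrayImage",
    "LabeledDataset",
    "CLASS_NAMES",
    "resize_to",
    "crop_roi",
    "equalize_histogram",
    "despeckle",
    "normalize_intensity",
    "balance_classes",
]

#: Plane labels 0..5 in fixed order.
CLASS_NAMES = (
    "brain",
    "abdomen",
    "femur",
    "thorax",
    "maternal cervix",
    "other",
)


@dataclass(frozen=True, eq=False)
class GrayImage:
    """A 2-D grayscale intensity matrix.

    Parameters
    ----------
    pixels
        2-D array.  ``uint8`` in 0..255 when ``normalized`` is False,
        float in [0, 1] when True.
    normalized
        Declared intensity range flag.
    """

    pixels: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if not np.all(np.isfinite(px.astype(np.float64))):
            raise ValueError("pixels contain non-finite values")
        if self.normalized:
            px = px.astype(np.float64)
            if px.min() < -1e-12 or px.max() > 1 + 1e-12:
                raise ValueError("normalized image must lie in [0, 1]")
        else:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("integer image must lie in 0..255")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabeledDataset:
    """An ordered collection of (image, integer label) records."""

    images: list
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 5):
            raise ValueError("labels must be integers in 0..5")

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=np.int64)
        return LabeledDataset([self.images[i] for i in idx], self.labels[idx])


def resize_to(
    image: GrayImage,
    target_h: int,
    target_w: int,
    preserve_aspect: bool = True,
) -> GrayImage:
    """Rescale to a standard resolution, optionally keeping aspect ratio.

    With ``preserve_aspect`` the image is scaled by the largest factor
    that fits inside the target frame and the remainder is zero-padded
    (bottom/right), so output dimensions always equal the targets.
    """
    if target_h < 1 or target_w < 1:
        raise ValueError(f"target dimensions must be positive, got ({target_h}, {target_w})")
    h, w = image.pixels.shape
    if preserve_aspect:
        s = min(target_h / h, target_w / w)
        new_h = max(1, round(h * s))
        new_w = max(1, round(w * s))
    else:
        new_h, new_w = target_h, target_w
    px = image.pixels.astype(np.float64)
    anti_alias = new_h < h or new_w < w
    out = _sk_resize(px, (new_h, new_w), order=1, anti_aliasing=anti_alias,
                     preserve_range=True, mode="edge")
    if new_h != target_h or new_w != target_w:
        frame = np.zeros((target_h, target_w), dtype=np.float64)
        frame[:new_h, :new_w] = out
        out = frame
    if image.normalized:
        return GrayImage(np.clip(out, 0.0, 1.0), normalized=True)
    return GrayImage(np.clip(np.rint(out), 0, 255).astype(np.uint8))


def crop_roi(image: GrayImage, x: int, y: int, h: int, w: int) -> GrayImage:
    """Extract the sub-rectangle [y, y+h) x [x, x+w) (0-based, half-open).

    ``x`` indexes columns and ``y`` rows, matching the usual (x, y)
    screen convention for region-of-interest boxes.
    """
    if h < 1 or w < 1:
        raise ValueError("crop height and width must be positive")
    if x < 0 or x + w > image.width:
        raise ValueError(
            f"crop x-range [{x}, {x + w}) exceeds image width {image.width}"
        )
    if y < 0 or y + h > image.height:
        raise ValueError(
            f"crop y-range [{y}, {y + h}) exceeds image height {image.height}"
        )
    return GrayImage(image.pixels[y : y + h, x : x + w].copy(), image.normalized)


def equalize_histogram(image: GrayImage) -> GrayImage:
    """Contrast enhancement by the 256-bin cumulative-histogram mapping.

    Each intensity v is remapped to round(255 * cdf(v)), a monotone
    transform of the empirical intensity CDF.  Only defined for integer
    images; equalize before normalizing to [0, 1].
    """
    if image.normalized:
        raise ValueError("equalize_histogram requires an integer-intensity image; "
                         "apply it before normalize_intensity")
    hist = np.bincount(image.pixels.ravel(), minlength=256)
    cdf = np.cumsum(hist) / image.pixels.size
    lut = np.rint(cdf * 255.0).astype(np.uint8)
    return GrayImage(lut[image.pixels])


def despeckle(image: GrayImage, window: int = 3) -> GrayImage:
    """Median filter with edge replication, suppressing speckle impulses.

    The median is a rank-order statistic, so the output range never
    exceeds the input range.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    out = ndimage.median_filter(image.pixels, size=window, mode="nearest")
    return GrayImage(out, image.normalized)


def normalize_intensity(image: GrayImage) -> GrayImage:
    """Affine rescale (p - min)/(max - min) onto [0, 1].

    A constant image maps to all zeros by convention.
    """
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return GrayImage(np.zeros_like(px), normalized=True)
    return GrayImage((px - lo) / (hi - lo), normalized=True)


def balance_classes(
    data: LabeledDataset,
    target_per_class: int,
    seed: int,
    classes: Sequence[int] | None = None,
) -> LabeledDataset:
    """Random over/undersampling to exactly ``target_per_class`` per class.

    Classes above the target are randomly subsampled without
    replacement (original order preserved among kept records); classes
    below it are topped up by random duplication of their own records.
    Deterministic for a fixed ``seed``.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    if classes is None:
        classes = sorted(data.class_counts())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(data.labels == c)
        if idx.size == 0:
            raise ValueError(f"class {c} has no records; cannot balance an empty class")
        if idx.size > target_per_class:
            sel = np.sort(rng.choice(idx.size, size=target_per_class, replace=False))
            keep.append(idx[sel])
        elif idx.size < target_per_class:
            extra = rng.choice(idx.size, size=target_per_class - idx.size, replace=True)
            keep.append(np.concatenate([idx, idx[extra]]))
        else:
            keep.append(idx)
    order = np.concatenate(keep)
    return data.subset(order)


# ---------------------------------------------------------------------------
# configurable preprocessing chain

@dataclass
class PreprocessConfig:
    """Stage toggles and parameters for the fixed-order chain
    resize -> crop -> equalize -> despeckle -> normalize."""

    stages: tuple[str, ...] = ("equalize", "despeckle", "normalize")
    target_h: int = 224
    target_w: int = 224
    preserve_aspect: bool = True
    crop: tuple[int, int, int, int] | None = None  # (x, y, h, w)
    despeckle_window: int = 3

    _ORDER = ("resize", "crop", "equalize", "despeckle", "normalize")

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(self._ORDER)
        if unknown:
            raise ValueError(f"unknown preprocessing stages: {sorted(unknown)}")


def preprocess_image(image: GrayImage, cfg: PreprocessConfig) -> GrayImage:
    """Run the enabled stages of the chain in their fixed order."""
    out = image
    for stage in cfg._ORDER:
        if stage not in cfg.stages:
            continue
        if stage == "resize":
            out = resize_to(out, cfg.target_h, cfg.target_w, cfg.preserve_aspect)
        elif stage == "crop" and cfg.crop is not None:
            x, y, h, w = cfg.crop
            out = crop_roi(out, x, y, h, w)
        elif stage == "equalize":
            out = equalize_histogram(out)
        elif stage == "despeckle":
            out = despeckle(out, cfg.despeckle_window)
        elif stage == "normalize":
            out = normalize_intensity(out)
    return out


def preprocess_dataset(data: LabeledDataset, cfg: PreprocessConfig) -> LabeledDataset:
    return LabeledDataset([preprocess_image(im, cfg) for im in data.images],
                          data.labels.copy())
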