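"""Seeded synthetic data: textured grayscale images and planted feature tables.

The image generator emulates the aspect of ultrasound data this toolkit
actually exploits — classes that differ in spatial gray-level
correlation structure, corrupted by multiplicative speckle — without
any claim of acoustic realism.  Each class is an anisotropic Gaussian
random field: white noise smoothed with an oriented Gaussian kernel
whose major-axis length sets the correlation length and whose
orientation sets the anisotropy, mapped to mid-gray +/- a contrast
swing and multiplied by (1 + speckle) with zero-mean Gaussian speckle
of configurable variance.  Short correlation lengths give fine, busy
textures (high GLCM contrast at distance 5); long ones give coarse,
slowly varying textures.

The table generator plants ``n_informative`` class-separated columns
(per-column random permutation of equally spaced class means, unit
noise) among pure-noise columns, and returns the ground-truth mask so
wrapper selection can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .imgproc import GrayImage, LabeledDataset
from .texture import FeatureTable

__all__ = [
    "TextureClassSpec",
    "PlantedTableSpec",
    "DEFAULT_CLASS_SPECS",
    "TABLE2_SCALED_COUNTS",
    "TABLE2_FULL_COUNTS",
    "generate_texture_image",
    "generate_dataset",
    "generate_feature_table",
]

#: Per-class image counts of the real screening collection (full scale)
#: and the 1/10-scale default used for fast synthetic experiments.
TABLE2_FULL_COUNTS = (3092, 711, 1040, 1718, 1626, 4213)
TABLE2_SCALED_COUNTS = (309, 71, 104, 172, 163, 421)


@dataclass(frozen=True)
class TextureClassSpec:
    correlation_length: float  # pixels, major axis of the smoothing kernel
    anisotropy_angle: float  # degrees, orientation of the major axis
    contrast_scale: float = 60.0  # gray levels of texture swing around mid-gray
    speckle_variance: float = 0.1  # variance of the multiplicative noise

    def __post_init__(self) -> None:
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1 pixel")
        if self.speckle_variance < 0:
            raise ValueError("speckle_variance must be >= 0")


#: Six distinct texture classes standing in for the six plane labels:
#: correlation length 2..12 px and orientation stepped by 30 degrees.
DEFAULT_CLASS_SPECS = tuple(
    TextureClassSpec(correlation_length=cl, anisotropy_angle=ang)
    for cl, ang in zip((2, 4, 6, 8, 10, 12), (0, 30, 60, 90, 120, 150))
)


@dataclass(frozen=True)
class PlantedTableSpec:
    n_per_class: int = 50
    n_informative: int = 5
    n_noise: int = 40
    effect_size: float = 3.0  # class-mean spacing in units of the unit noise sd
    n_classes: int = 6
    seed: int = 0


def _oriented_kernel(length: float, angle_deg: float) -> np.ndarray:
    """Anisotropic Gaussian kernel: sigma ``length`` along the oriented
    major axis, length/3 across it, truncated at 3 sigma."""
    sigma_u = float(length)
    sigma_v = max(length / 3.0, 0.5)
    half = max(int(np.ceil(3.0 * sigma_u)), 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    th = np.deg2rad(angle_deg)
    u = xx * np.cos(th) + yy * np.sin(th)
    v = -xx * np.sin(th) + yy * np.cos(th)
    k = np.exp(-(u**2) / (2 * sigma_u**2) - (v**2) / (2 * sigma_v**2))
    return k / k.sum()


def generate_texture_image(
    spec: TextureClassSpec, h: int, w: int, seed: int | np.random.Generator
) -> GrayImage:
    """One textured frame of shape (h, w); deterministic given the seed."""
    if h < 32 or w < 32:
        raise ValueError("image dimensions must be >= 32")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kernel = _oriented_kernel(spec.correlation_length, spec.anisotropy_angle)
    pad = kernel.shape[0] // 2
    noise = rng.standard_normal((h + 2 * pad, w + 2 * pad))
    field = fftconvolve(noise, kernel, mode="same")[pad : pad + h, pad : pad + w]
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    base = 128.0 + spec.contrast_scale * field
    speckle = rng.normal(0.0, np.sqrt(spec.speckle_variance), size=(h, w))
    img = base * (1.0 + speckle)
    return GrayImage(np.clip(np.rint(img), 0, 255).astype(np.uint8))


def generate_dataset(
    specs: Sequence[TextureClassSpec] = DEFAULT_CLASS_SPECS,
    n_per_class: int | None = None,
    imbalance_counts: Sequence[int] | None = None,
    h: int = 64,
    w: int = 64,
    seed: int = 0,
) -> LabeledDataset:
    """Labeled images for the six texture classes.

    Give either a uniform ``n_per_class`` or explicit per-class
    ``imbalance_counts``; with neither, the 1/10-scale imbalanced
    counts are used.
    """
    if len(specs) != 6:
        raise ValueError("exactly 6 class specs are required")
    if n_per_class is not None and imbalance_counts is not None:
        raise ValueError("give n_per_class or imbalance_counts, not both")
    if n_per_class is not None:
        counts = (n_per_class,) * 6
    elif imbalance_counts is not None:
        if len(imbalance_counts) != 6:
            raise ValueError("imbalance_counts must have 6 entries")
        counts = tuple(int(c) for c in imbalance_counts)
    else:
        counts = TABLE2_SCALED_COUNTS
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label, (spec, count) in enumerate(zip(specs, counts)):
        for _ in range(count):
            child = int(rng.integers(0, 2**31))
            images.append(generate_texture_image(spec, h, w, child))
            labels.append(label)
    return LabeledDataset(images, np.asarray(labels))


def generate_feature_table(spec: PlantedTableSpec) -> tuple[FeatureTable, np.ndarray]:
    """Planted-signal table and its ground-truth informative mask.

    Informative column k shifts the mean of one designated class
    (class 1 + (k mod (n_classes - 1))) by ``effect_size`` relative to
    all other classes, with unit Gaussian noise everywhere; noise
    columns are class-independent N(0, 1).  With the defaults (6
    classes, 5 informative columns) this is a one-hot code: the class
    centroids are pairwise at least ``effect_size`` apart, and every
    informative column is individually necessary — removing it makes
    its designated class indistinguishable from the baseline class —
    so wrapper selection can be scored for exact recovery.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_informative + spec.n_noise
    n = spec.n_per_class * spec.n_classes
    y = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    X = rng.standard_normal((n, p))
    informative = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    for k, col in enumerate(informative):
        target_class = 1 + (k % (spec.n_classes - 1))
        X[y == target_class, col] += spec.effect_size
    mask = np.zeros(p, dtype=bool)
    mask[informative] = True
    names = [
        f"{'inf' if mask[k] else 'noise'}_{k}" for k in range(p)
    ]
    return FeatureTable(X, y, names), mask
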