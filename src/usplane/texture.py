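"""Gray-level co-occurrence matrices and Haralick texture descriptors.

A GLCM P(i, j) is the normalized joint frequency with which gray
levels i and j co-occur at a fixed pixel displacement (distance d,
orientation theta).  Fine textures decorrelate quickly with d, coarse
textures slowly, so scalar summaries of P separate tissue textures that
raw intensities do not.

The extractor quantizes a normalized image to ``levels`` gray levels,
builds one symmetric normalized GLCM per angle at a single distance,
and computes nine descriptors per matrix.  Under the defaults
(distance 5, angles {0, 30, 45, 90, 135} degrees, 9 descriptors) every
image yields a 45-element feature vector.

Descriptor definitions (P normalized and symmetric, indices 0-based,
marginal moments taken over the i-marginal, which equals the j-marginal
by symmetry):

==============  =====================================================
contrast        sum P(i,j) (i-j)^2
dissimilarity   sum P(i,j) |i-j|
homogeneity     sum P(i,j) / (1 + (i-j)^2)
energy          sum P(i,j)^2
asm             sum P(i,j)^4
correlation     (sum i j P(i,j) - mu_i mu_j) / (sigma_i sigma_j)
entropy         -sum P(i,j) log10 P(i,j),   0 log 0 := 0
mean            mu_i = sum i P(i,j)
variance        sigma_i^2 = sum P(i,j) (i - mu_i)^2
==============  =====================================================

Notes on two deliberate conventions: ``asm`` is the fourth-power sum
(not the classical squared sum, which is ``energy`` here), and entropy
uses base-10 logarithms (configurable).  Correlation of a GLCM with a
zero marginal standard deviation is defined as 0.  The marginal
standard deviation itself is excluded from the feature set: under a
symmetric GLCM it is a deterministic monotone transform of the variance
and carries no independent information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .imgproc import GrayImage, LabeledDataset, normalize_intensity

__all__ = [
    "DESCRIPTOR_NAMES",
    "GLCM",
    "TextureConfig",
    "FeatureVector",
    "FeatureTable",
    "DegenerateInputError",
    "quantize_levels",
    "compute_glcm",
    "haralick_descriptors",
    "extract_feature_vector",
    "build_feature_table",
]

DESCRIPTOR_NAMES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "asm",
    "correlation",
    "entropy",
    "mean",
    "variance",
)


class DegenerateInputError(ValueError):
    """Image too small to contain a single co-occurring pixel pair."""


@dataclass(frozen=True, eq=False)
class GLCM:
    """Normalized symmetric co-occurrence matrix for one (d, angle) pair."""

    P: np.ndarray
    levels: int
    distance: int
    angle: float  # degrees

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("GLCM must be square")
        if P.min() < 0:
            raise ValueError("GLCM entries must be nonnegative")
        if abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must sum to 1")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class TextureConfig:
    distance: int = 5
    angles: tuple[float, ...] = (0.0, 30.0, 45.0, 90.0, 135.0)
    levels: int = 8
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES
    entropy_log_base: float = 10.0

    def __post_init__(self) -> None:
        unknown = set(self.descriptors) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    @property
    def n_features(self) -> int:
        return len(self.angles) * len(self.descriptors)

    def feature_names(self) -> list[str]:
        return [
            f"a{int(a) if float(a).is_integer() else a}_{d}"
            for a in self.angles
            for d in self.descriptors
        ]


@dataclass(frozen=True, eq=False)
class FeatureVector:
    values: np.ndarray
    config: TextureConfig

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size != self.config.n_features:
            raise ValueError("feature vector length does not match config")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass
class FeatureTable:
    """n x p descriptor matrix with class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X rows must match y length")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.y)
        return df

    def to_csv(self, path) -> None:
        # repr-precision floats round-trip bit-exactly
        self.to_dataframe().to_csv(path, index=False, float_format=None)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        if "label" not in df.columns:
            raise ValueError("feature CSV must have a 'label' column")
        names = [c for c in df.columns if c != "label"]
        return cls(df[names].to_numpy(np.float64), df["label"].to_numpy(np.int64), names)


def quantize_levels(image: GrayImage, levels: int) -> np.ndarray:
    """Uniformly bin a normalized [0, 1] image into integer gray levels.

    Value 1.0 is assigned to the top bin ``levels - 1``.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not image.normalized:
        raise ValueError("quantize_levels expects a normalized [0, 1] image")
    q = np.floor(image.pixels * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def compute_glcm(levels_matrix: np.ndarray, d: int, angle: float,
                 n_levels: int | None = None) -> GLCM:
    """Symmetric, normalized co-occurrence matrix at displacement (d, angle).

    The displacement vector is the rounded (d sin(theta), d cos(theta))
    pixel offset (Haralick convention: 0 degrees is the horizontal
    neighbor); co-occurrences are accumulated in both directions and the
    counts divided by the total number of pairs.
    """
    lm = np.asarray(levels_matrix)
    if lm.ndim != 2:
        raise ValueError("level matrix must be 2-D")
    if n_levels is None:
        n_levels = int(lm.max()) + 1
    counts = graycomatrix(
        lm.astype(np.uint8),
        distances=[d],
        angles=[np.deg2rad(angle)],
        levels=n_levels,
        symmetric=True,
        normed=False,
    )[:, :, 0, 0].astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError(
            f"image of shape {lm.shape} contains no pixel pair at "
            f"distance {d}, angle {angle} degrees"
        )
    return GLCM(counts / total, n_levels, d, angle)


def haralick_descriptors(
    glcm: GLCM,
    descriptors: Sequence[str] = DESCRIPTOR_NAMES,
    entropy_log_base: float = 10.0,
) -> np.ndarray:
    """The requested scalar texture descriptors of one GLCM, in order."""
    P = glcm.P
    n = P.shape[0]
    i = np.arange(n)[:, None].astype(np.float64)
    j = np.arange(n)[None, :].astype(np.float64)
    diff = i - j

    mu_i = float(np.sum(i * P))
    var_i = float(np.sum(P * (i - mu_i) ** 2))
    sd_i = np.sqrt(var_i)
    # symmetric P => j-marginal moments coincide with the i-marginal ones
    if sd_i > 0:
        corr = float((np.sum(i * j * P) - mu_i * mu_i) / (sd_i * sd_i))
    else:
        corr = 0.0
    pos = P > 0
    ent = float(-np.sum(P[pos] * np.log(P[pos]) / np.log(entropy_log_base)))

    all_values = {
        "contrast": float(np.sum(P * diff**2)),
        "dissimilarity": float(np.sum(P * np.abs(diff))),
        "homogeneity": float(np.sum(P / (1.0 + diff**2))),
        "energy": float(np.sum(P**2)),
        "asm": float(np.sum(P**4)),
        "correlation": corr,
        "entropy": ent,
        "mean": mu_i,
        "variance": var_i,
    }
    return np.array([all_values[name] for name in descriptors], dtype=np.float64)


def extract_feature_vector(image: GrayImage, cfg: TextureConfig = TextureConfig()) -> FeatureVector:
    """Quantize, build one GLCM per configured angle, and concatenate the
    per-angle descriptor blocks (angle-major ordering)."""
    if not image.normalized:
        image = normalize_intensity(image)
    q = quantize_levels(image, cfg.levels)
    blocks = []
    for angle in cfg.angles:
        glcm = compute_glcm(q, cfg.distance, angle, n_levels=cfg.levels)
        blocks.append(haralick_descriptors(glcm, cfg.descriptors, cfg.entropy_log_base))
    return FeatureVector(np.concatenate(blocks), cfg)


def build_feature_table(data: LabeledDataset, cfg: TextureConfig = TextureConfig()) -> FeatureTable:
    """Extract one feature vector per image; row order follows the dataset."""
    if len(data) == 0:
        raise ValueError("dataset is empty")
    rows = []
    failures: list[tuple[int, str]] = []
    for k, im in enumerate(data.images):
        try:
            rows.append(extract_feature_vector(im, cfg).values)
        except Exception as exc:  # aggregate, report all failing indices
            failures.append((k, str(exc)))
    if failures:
        detail = "; ".join(f"image {k}: {msg}" for k, msg in failures[:5])
        raise DegenerateInputError(
            f"feature extraction failed for {len(failures)} image(s): {detail}"
        )
    return FeatureTable(np.vstack(rows), data.labels.copy(), cfg.feature_names())
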