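"""Image color-moment and co-occurrence texture features.

From each product image a central 400×400 block is cropped and described by
52 features:

* **36 color features** — mean, sample standard deviation, skewness and
  kurtosis of the nine channels R, G, B, H, S, V, L*, a*, b* (HSV via the
  hexcone transform, CIELAB via sRGB → XYZ with the D65 2° white point).
* **16 texture features** — scalar descriptors of the gray-level
  co-occurrence matrix (GLCM), averaged over the four direction offsets
  0°, 45°, 90°, 135° at distance one pixel.

Conventions (fixed so outputs are reproducible): grayscale weights
0.2989/0.5870/0.1140; linear quantization of [0, 1] into 8 gray levels;
each directional matrix symmetrized before averaging; logarithms base 2
(entropies in bits); sum-variance centered on the sum-average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv, rgb2lab

from .simulate import ImageSample
from .tables import FeatureTable

#: (Δrow, Δcol) offsets for 0°, 45°, 90°, 135° at distance 1.
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
DEFAULT_LEVELS = 8

CHANNEL_NAMES = ("R", "G", "B", "H", "S", "V", "L", "As", "Bs")
STAT_NAMES = ("ave", "std", "skew", "kurt")
COLOR_FEATURE_NAMES = tuple(
    f"{ch}_{st}" for ch in CHANNEL_NAMES for st in STAT_NAMES
)
TEXTURE_FEATURE_NAMES = (
    "Entropy", "Energy", "Inertia", "Correlation", "Homogeneity",
    "Dissimilarity", "Sum_of_squares", "Sum_average", "Sum_variance",
    "Sum_entropy", "Difference_variance", "Difference_entropy",
    "Cluster_shade", "Cluster_prominence", "Inverse_difference_moment",
    "Maximum_probability",
)
IMAGE_FEATURE_NAMES = COLOR_FEATURE_NAMES + TEXTURE_FEATURE_NAMES

_GRAY_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])


@dataclass
class ImageBlock:
    """A square RGB block cropped from an image center."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("block must be H×W×3")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("block intensities must lie in [0, 1]")


@dataclass
class GLCMatrix:
    """A (normalized, symmetric) gray-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    normalized: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("matrix must be levels × levels")


def crop_center_block(image: ImageSample | np.ndarray, size: int = 400) -> ImageBlock:
    """Axis-aligned central crop; odd residuals go to the bottom/right."""
    pixels = image.pixels if isinstance(image, ImageSample) else np.asarray(image)
    h, w = pixels.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}×{w} is smaller than crop size {size}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return ImageBlock(pixels[r0:r0 + size, c0:c0 + size])


def _channel_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sample std (n−1), skewness m3/m2^1.5, kurtosis m4/m2² (normal ⇒ 3)."""
    x = x.ravel()
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d * d))
    std = float(x.std(ddof=1))
    if m2 < 1e-12:
        return mean, std, 0.0, 0.0
    m3 = float(np.mean(d ** 3))
    m4 = float(np.mean(d ** 4))
    return mean, std, m3 / m2 ** 1.5, m4 / m2 ** 2


def color_statistics(block: ImageBlock) -> pd.Series:
    """The 36 channel-moment color features of a block.

    Channels are R, G, B (raw), H, S, V (each in [0, 1]) and CIELAB L
    (0–100), a, b — the latter named ``As``/``Bs`` in feature columns.
    """
    rgb = block.pixels
    hsv = rgb2hsv(rgb)
    lab = rgb2lab(rgb)
    channels = np.concatenate([rgb, hsv, lab], axis=2)
    out: dict[str, float] = {}
    for k, ch in enumerate(CHANNEL_NAMES):
        stats = _channel_moments(channels[:, :, k])
        for st, val in zip(STAT_NAMES, stats):
            out[f"{ch}_{st}"] = val
    return pd.Series(out)


def quantize_gray(rgb: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Luma grayscale, linearly quantized into ``levels`` equal bins of [0, 1]."""
    gray = rgb @ _GRAY_WEIGHTS
    q = np.floor(gray * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def compute_glcm(
    block: ImageBlock | np.ndarray,
    levels: int = DEFAULT_LEVELS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> GLCMatrix:
    """Direction-averaged, symmetrized, normalized co-occurrence matrix.

    For every offset (Δrow, Δcol) each in-bounds pixel pair
    ``(I[p,q], I[p+Δrow, q+Δcol])`` is counted; each directional matrix is
    symmetrized as ``P + Pᵀ``, the matrices are averaged over the offsets,
    and the result is normalized to sum to one.
    """
    if levels < 2:
        raise ValueError("levels must be ≥ 2")
    pixels = block.pixels if isinstance(block, ImageBlock) else np.asarray(block)
    if pixels.ndim == 3:
        q = quantize_gray(pixels, levels)
    else:  # pre-quantized gray levels
        q = np.asarray(pixels, dtype=np.intp)
        if q.max() >= levels or q.min() < 0:
            raise ValueError("gray levels out of range for the given levels")
    h, w = q.shape
    acc = np.zeros((levels, levels))
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts = np.bincount(a * levels + b, minlength=levels * levels)
        p = counts.reshape(levels, levels).astype(float)
        acc += p + p.T
    total = acc.sum()
    if total > 0:
        acc /= total
    return GLCMatrix(matrix=acc, levels=levels, offsets=tuple(offsets),
                     normalized=True)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick16(glcm: GLCMatrix) -> pd.Series:
    """The 16 texture descriptors of a normalized symmetric GLCM.

    Level indices are 1-based. Marginal mean/variance use the row marginal
    (equal to the column marginal by symmetry); correlation is defined as 0
    when the marginal variance vanishes (constant image).
    """
    p = glcm.matrix
    if not glcm.normalized or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("haralick16 requires a normalized GLCM")
    n = glcm.levels
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    # distributions of i+j (2..2n) and |i−j| (0..n−1)
    sums = ii + jj
    diffs = np.abs(ii - jj)
    p_sum = np.bincount(sums.ravel(), weights=p.ravel(), minlength=2 * n + 1)[2:]
    p_diff = np.bincount(diffs.ravel(), weights=p.ravel(), minlength=n)
    k_sum = np.arange(2, 2 * n + 1)
    k_diff = np.arange(n)

    sum_average = float((k_sum * p_sum).sum())
    diff_mean = float((k_diff * p_diff).sum())
    corr = 0.0 if var < 1e-12 else float(
        (((ii - mu) * (jj - mu)) * p).sum() / var
    )
    return pd.Series({
        "Entropy": _entropy_bits(p.ravel()),
        "Energy": float((p ** 2).sum()),
        "Inertia": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Sum_of_squares": float(((ii - mu) ** 2 * p).sum()),
        "Sum_average": sum_average,
        "Sum_variance": float(((k_sum - sum_average) ** 2 * p_sum).sum()),
        "Sum_entropy": _entropy_bits(p_sum),
        "Difference_variance": float(((k_diff - diff_mean) ** 2 * p_diff).sum()),
        "Difference_entropy": _entropy_bits(p_diff),
        "Cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "Cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "Inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Maximum_probability": float(p.max()),
    })


def image_feature_table(
    images: list[ImageSample],
    levels: int = DEFAULT_LEVELS,
    crop_size: int = 400,
    sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Extract the 52-feature battery (36 color + 16 texture) per image."""
    rows = []
    labels = []
    for k, img in enumerate(images):
        try:
            block = crop_center_block(img, crop_size)
        except ValueError as exc:
            raise ValueError(f"sample {k}: {exc}") from exc
        color = color_statistics(block)
        texture = haralick16(compute_glcm(block, levels))
        rows.append(pd.concat([color, texture]))
        labels.append(img.grade)
    if sample_ids is None:
        sample_ids = [f"sample_{i:03d}" for i in range(len(images))]
    if rows:
        values = pd.DataFrame(rows)
        values.index = pd.Index(sample_ids)
    else:
        values = pd.DataFrame(columns=list(IMAGE_FEATURE_NAMES))
    return FeatureTable(values, pd.Series(labels, index=values.index,
                                          dtype=object),
                        provenance="image")
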