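"""CIELAB + co-occurrence contrast features from product photographs.

Each photograph is reduced to four numbers: mean L*, a*, b* over the region
of interest, and the gray-level co-occurrence (GLCM) contrast of the
quantized L* channel. Conversion assumes sRGB input under the D65
illuminant. GLCM defaults — 16 gray levels, offsets right and down,
symmetric, normalized — are deliberate choices recorded in
:data:`DEFAULT_CONFIG`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2lab
from skimage.feature import graycomatrix, graycoprops

__all__ = [
    "FeatureConfig",
    "ImageFeatureVector",
    "DEFAULT_CONFIG",
    "load_and_standardize",
    "rgb_to_lab",
    "mean_lab",
    "quantize_gray",
    "glcm_contrast",
    "extract_features",
    "extract_directory",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Standardization and GLCM settings applied to every image."""

    resolution: tuple[int, int] = (640, 480)  # (width, height)
    resize: bool = True
    levels: int = 16
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0))  # (drow, dcol)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class ImageFeatureVector:
    sample_id: str
    L_star: float
    a_star: float
    b_star: float
    contrast: float

    def __post_init__(self) -> None:
        vals = (self.L_star, self.a_star, self.b_star, self.contrast)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("image features must be finite")
        if not (0.0 <= self.L_star <= 100.0 + 1e-9):
            raise ValueError("L* must lie in [0, 100]")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


def load_and_standardize(
    path,
    roi: tuple[int, int, int, int] | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Read an 8-bit image, optionally crop ``roi`` (left, top, right, bottom),
    resize to the configured resolution, and scale to float RGB in [0, 1]."""
    with Image.open(path) as img:
        img = img.convert("RGB")
        if roi is not None:
            left, top, right, bottom = roi
            if right <= left or bottom <= top:
                raise ValueError("roi has zero or negative area")
            img = img.crop(roi)
        if config.resize:
            img = img.resize(config.resolution, resample=Image.BILINEAR)
        arr = np.asarray(img, dtype=np.float64) / 255.0
    if arr.size == 0:
        raise ValueError(f"image {path} has zero area")
    return arr


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Per-pixel sRGB -> XYZ (D65) -> CIELAB."""
    return rgb2lab(image)


def mean_lab(lab: np.ndarray) -> tuple[float, float, float]:
    """Arithmetic mean of each Lab channel."""
    means = lab.reshape(-1, 3).mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def quantize_gray(gray: np.ndarray, levels: int, vmax: float = 100.0) -> np.ndarray:
    """Uniformly bin a grayscale array on [0, vmax] into integer levels."""
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    q = np.floor(np.clip(gray, 0, vmax) / vmax * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm_contrast(
    quantized: np.ndarray,
    levels: int = DEFAULT_CONFIG.levels,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_CONFIG.offsets,
) -> float:
    """Contrast sum_ij P(i,j)(i-j)^2 of the symmetric, normalized GLCM
    averaged over the given (drow, dcol) offsets."""
    if quantized.ndim != 2:
        raise ValueError("expected a 2-D quantized grayscale array")
    if quantized.max() >= levels:
        raise ValueError("quantized values exceed the stated level count")
    contrasts = []
    for drow, dcol in offsets:
        if abs(drow) >= quantized.shape[0] or abs(dcol) >= quantized.shape[1]:
            raise ValueError(f"offset {(drow, dcol)} larger than the image")
        # skimage parameterizes offsets as distance/angle:
        # angle 0 -> (0, +d); angle -pi/2 -> (+d, 0)
        if (drow, dcol) == (0, 1):
            dist, angle = 1, 0.0
        elif (drow, dcol) == (1, 0):
            dist, angle = 1, -np.pi / 2
        else:
            dist = int(np.hypot(drow, dcol))
            angle = float(np.arctan2(-drow, dcol))
        glcm = graycomatrix(
            quantized, [dist], [angle], levels=levels, symmetric=True, normed=True
        )
        contrasts.append(graycoprops(glcm, "contrast")[0, 0])
    return float(np.mean(contrasts))


def extract_features(
    path,
    sample_id: str | None = None,
    roi: tuple[int, int, int, int] | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> ImageFeatureVector:
    """Full per-image pipeline: standardize, convert, average, GLCM contrast."""
    image = load_and_standardize(path, roi=roi, config=config)
    lab = rgb_to_lab(image)
    L, a, b = mean_lab(lab)
    quantized = quantize_gray(lab[..., 0], config.levels)
    contrast = glcm_contrast(quantized, config.levels, config.offsets)
    if sample_id is None:
        sample_id = Path(path).stem
    return ImageFeatureVector(
        sample_id=sample_id, L_star=L, a_star=a, b_star=b, contrast=contrast
    )


def extract_directory(
    directory,
    pattern: str = "*.png",
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One feature row per image in ``directory`` (sorted by filename)."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no images matching {pattern!r} in {directory}")
    rows = [asdict(extract_features(p, config=config)) for p in paths]
    return pd.DataFrame(rows, columns=["sample_id", "L_star", "a_star", "b_star", "contrast"])
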