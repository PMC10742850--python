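"""Synthetic image-feature/texture datasets and PNG fixture images.

The generator draws a monotone latent (think of it as processing intensity):
as it rises, L* falls and b* rises, a* stays negative, contrast drifts
upward. Each texture attribute is a smooth nonlinear map of the features
plus Gaussian noise, so a trained network has real signal to find. Fixture
tiles (flat color and checkerboard) come with analytically known mean Lab
and co-occurrence contrast for end-to-end feature-extraction checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2lab

from .texture_model import FEATURE_COLUMNS, TEXTURE_ATTRIBUTES

__all__ = ["SynthDatasetSpec", "generate_dataset", "generate_fixture_images"]


#: target = alpha*(100 - L*) + beta*b*^2 + gamma*contrast + delta*a* (+ noise)
DEFAULT_COEFFS: dict[str, tuple[float, float, float, float]] = {
    "hardness": (0.9, 0.04, 0.5, -0.3),
    "stickiness": (0.3, 0.02, 0.2, -0.6),
    "chewiness": (0.7, 0.05, 0.4, -0.2),
    "adhesiveness": (0.2, 0.01, 0.6, -0.4),
    "resilience": (0.5, 0.03, 0.3, -0.1),
    "cohesion": (0.4, 0.02, 0.1, -0.5),
    "elasticity": (0.6, 0.01, 0.2, -0.3),
}


@dataclass(frozen=True)
class SynthDatasetSpec:
    n_samples: int = 118
    L_range: tuple[float, float] = (45.0, 80.0)   # decreasing in the latent
    a_range: tuple[float, float] = (-12.0, -2.0)  # stays negative
    b_range: tuple[float, float] = (10.0, 35.0)   # increasing in the latent
    contrast_range: tuple[float, float] = (1.0, 9.0)
    coeffs: dict = field(default_factory=lambda: dict(DEFAULT_COEFFS))
    noise_sd: float = 0.0
    feature_jitter: float = 0.03  # relative scatter around the latent trend
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0 or self.feature_jitter < 0:
            raise ValueError("noise_sd and feature_jitter must be >= 0")
        if self.a_range[1] >= 0:
            raise ValueError("a* range must be negative")
        if self.b_range[0] <= 0:
            raise ValueError("b* range must be positive")


def _target(features: np.ndarray, coeffs: tuple[float, float, float, float]) -> np.ndarray:
    L, a, b, contrast = features.T
    alpha, beta, gamma, delta = coeffs
    return alpha * (100.0 - L) + beta * b**2 + gamma * contrast + delta * a


def generate_dataset(spec: SynthDatasetSpec) -> pd.DataFrame:
    """Feature/attribute table with spec.n_samples rows, seeded."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(0.0, 1.0, spec.n_samples)  # latent processing intensity

    def trend(lo: float, hi: float, up: bool) -> np.ndarray:
        base = lo + (hi - lo) * (u if up else 1.0 - u)
        jitter = rng.normal(0.0, spec.feature_jitter * (hi - lo), spec.n_samples)
        return np.clip(base + jitter, min(lo, hi), max(lo, hi))

    L = trend(*spec.L_range, up=False)
    a = trend(*spec.a_range, up=True)
    b = trend(*spec.b_range, up=True)
    contrast = trend(*spec.contrast_range, up=True)
    features = np.column_stack([L, a, b, contrast])

    data = {
        "sample_id": [f"synth_{i:03d}" for i in range(spec.n_samples)],
        "L_star": L,
        "a_star": a,
        "b_star": b,
        "contrast": contrast,
    }
    for name in TEXTURE_ATTRIBUTES:
        coeffs = spec.coeffs.get(name, DEFAULT_COEFFS[name])
        y = _target(features, coeffs)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, spec.n_samples)
        data[name] = y
    return pd.DataFrame(data)


def generate_fixture_images(
    out_dir,
    n_flat: int = 6,
    n_checker: int = 2,
    size: tuple[int, int] = (640, 480),  # (width, height): matches the
    # default standardization resolution so resize is the identity
    levels: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Write flat-color and checkerboard PNG tiles plus a truth table.

    Flat tiles have zero co-occurrence contrast and a mean Lab equal to the
    Lab of their single color. Checkerboards alternate two gray values that
    quantize (L* on [0,100], ``levels`` bins) to 0 and levels-1, so their
    contrast under unit horizontal/vertical offsets is (levels-1)^2.
    Returns the truth table, also written to ``truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    w, h = size  # PIL convention

    for i in range(n_flat):
        rgb = rng.integers(30, 226, 3)  # avoid clipping extremes
        tile = np.full((h, w, 3), rgb, dtype=np.uint8)
        name = f"flat_{i:02d}.png"
        Image.fromarray(tile).save(out / name)
        lab = rgb2lab(tile[:1, :1, :] / 255.0)[0, 0]
        rows.append(
            {
                "sample_id": Path(name).stem,
                "file": name,
                "L_star": float(lab[0]),
                "a_star": float(lab[1]),
                "b_star": float(lab[2]),
                "contrast": 0.0,
            }
        )

    # gray values quantizing to the extreme bins: L*=0 (black) and L*=100 (white)
    for i in range(n_checker):
        rowidx, colidx = np.indices((h, w))
        checker = ((rowidx + colidx) % 2).astype(np.uint8) * 255
        tile = np.stack([checker] * 3, axis=-1)
        name = f"checker_{i:02d}.png"
        Image.fromarray(tile).save(out / name)
        black = rgb2lab(np.zeros((1, 1, 3)))[0, 0]
        white = rgb2lab(np.ones((1, 1, 3)))[0, 0]
        mean_lab = (black + white) / 2.0
        rows.append(
            {
                "sample_id": Path(name).stem,
                "file": name,
                "L_star": float(mean_lab[0]),
                "a_star": float(mean_lab[1]),
                "b_star": float(mean_lab[2]),
                "contrast": float((levels - 1) ** 2),
            }
        )

    truth = pd.DataFrame(rows)
    truth.to_csv(out / "truth.csv", index=False)
    return truth
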