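"""Feed-rate balance and linear calibration curves.

Two small pieces of plumbing every run depends on: the water-feed mass
balance that converts a target moisture content into a water feeding rate,
and ordinary-least-squares maps between a measured feature (a color channel,
a feeder rpm) and a physical quantity (tracer mg/g, g/min).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, FeedSpecError

__all__ = [
    "FeedSpec",
    "CalibrationCurve",
    "water_feed_rate",
    "fit_linear_map",
    "invert_standard_curve",
]


@dataclass(frozen=True)
class FeedSpec:
    """Material feed rate plus initial and target moisture fractions."""

    v_mf: float  # material feed, g/min
    c_in: float  # initial moisture, fraction in [0, 1)
    c_ex: float  # expected moisture, fraction in [0, 1)

    def __post_init__(self) -> None:
        if not (0 <= self.c_in < 1):
            raise FeedSpecError("c_in must lie in [0, 1)")
        if not (0 <= self.c_ex < 1):
            raise FeedSpecError("c_ex must lie in [0, 1); c_ex = 1 is a dry-mass singularity")
        if self.c_ex < self.c_in:
            raise FeedSpecError("c_ex below c_in would require removing water")
        if self.v_mf < 0:
            raise FeedSpecError("v_mf must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """y = slope * x + intercept with the fit's squared Pearson correlation."""

    slope: float
    intercept: float
    r_squared: float
    kind: Literal["standard_curve", "feed_map"] = "standard_curve"

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls(**json.load(fh))


def water_feed_rate(spec: FeedSpec) -> float:
    """Water feed (g/min) raising moisture from c_in to c_ex at material feed v_mf.

    V_wf = (C_ex - C_in) / (1 - C_ex) * V_mf
    """
    return (spec.c_ex - spec.c_in) / (1.0 - spec.c_ex) * spec.v_mf


def fit_linear_map(
    x, y, kind: Literal["standard_curve", "feed_map"] = "standard_curve"
) -> CalibrationCurve:
    """Ordinary least squares y on x; needs >= 3 points and non-constant x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise DegenerateFitError("need at least 3 points for a calibration fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        kind=kind,
    )


def invert_standard_curve(
    curve: CalibrationCurve, feature_value: float
) -> tuple[float, bool]:
    """Concentration (mg/g) for a measured feature value.

    Returns (concentration, clipped); negative solutions are clipped to 0
    with clipped=True since concentrations below blank are read noise.
    """
    if curve.slope == 0:
        raise DegenerateFitError("curve slope is zero; cannot invert")
    conc = (feature_value - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return conc, False
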