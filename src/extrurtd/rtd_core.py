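"""Residence-time-distribution analysis of a pulse-tracer concentration curve.

Given tracer concentration sampled over time at the extruder outlet, this
module computes the exit-age density E(t), the cumulative distribution F(t),
the mean residence time (MRT), the variance of the distribution, their
dimensionless forms, and the Peclet number obtained by inverting the
closed-vessel axial-dispersion relation

    sigma_theta^2 = 2/Pe - (2/Pe^2) * (1 - exp(-Pe)).

All integrals use the segment-sum discretization sum_i C_i * dt_i with
dt_i = t_i - t_{i-1} and dt_1 = t_2 - t_1; a trapezoid mode is available
via ``quadrature="trapezoid"`` for comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .errors import (
    NumericalInconsistencyError,
    PecletDomainError,
    UnnormalizableSeriesError,
)

__all__ = [
    "TracerSeries",
    "RTDCurves",
    "RTDSummary",
    "segment_widths",
    "normalize_to_E",
    "cumulative_F",
    "mean_residence_time",
    "rtd_variance",
    "dimensionless",
    "peclet_forward",
    "solve_peclet",
    "analyze_run",
    "relative_change",
    "trim_trailing_baseline",
]

Quadrature = Literal["segment", "trapezoid"]

#: Trailing samples below baseline + TRIM_EPS (mg/g) are considered colorless.
TRIM_EPS = 1e-6


@dataclass(frozen=True)
class TracerSeries:
    """One pulse-response run: tracer concentration (mg/g) vs time (s)."""

    times: np.ndarray
    concentrations: np.ndarray
    run_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D and equally long")
        if t.size < 2:
            raise ValueError("a tracer series needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise ValueError("times and concentrations must be finite")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.any(c > 0):
            raise UnnormalizableSeriesError(
                f"run {self.run_label!r}: all concentrations are zero"
            )

    def shifted(self, dt: float) -> "TracerSeries":
        return TracerSeries(self.times + dt, self.concentrations, self.run_label)


@dataclass
class RTDCurves:
    """E/F curves in real and dimensionless time for one run."""

    times: np.ndarray
    E: np.ndarray
    F: np.ndarray | None = None
    theta: np.ndarray | None = None
    E_theta: np.ndarray | None = None
    F_theta: np.ndarray | None = None


@dataclass
class RTDSummary:
    """Scalar RTD descriptors plus the curves they were derived from."""

    mrt: float
    variance: float
    sigma_theta2: float
    peclet: float | None
    peclet_solvable: bool
    curves: RTDCurves
    run_label: str = ""

    def to_dict(self) -> dict:
        return {
            "run_label": self.run_label,
            "mrt_s": self.mrt,
            "variance_s2": self.variance,
            "sigma_theta2": self.sigma_theta2,
            "peclet": self.peclet,
            "peclet_solvable": self.peclet_solvable,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def segment_widths(times: np.ndarray) -> np.ndarray:
    """dt_i = t_i - t_{i-1}, with the first width copied from the second."""
    t = np.asarray(times, dtype=float)
    dt = np.empty_like(t)
    dt[1:] = np.diff(t)
    dt[0] = dt[1] if t.size > 1 else 0.0
    return dt


def _effective_concentration(series: TracerSeries, baseline: float) -> np.ndarray:
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    if baseline >= series.concentrations.max():
        raise UnnormalizableSeriesError(
            "baseline is at or above the peak concentration"
        )
    return np.clip(series.concentrations - baseline, 0.0, None)


def _weights(series: TracerSeries, baseline: float, quadrature: Quadrature) -> np.ndarray:
    """Per-sample integration weight C_i * w_i for the chosen quadrature."""
    c = _effective_concentration(series, baseline)
    if quadrature == "segment":
        return c * segment_widths(series.times)
    if quadrature == "trapezoid":
        dt = np.diff(series.times)
        w = np.zeros_like(c)
        w[:-1] += dt / 2.0
        w[1:] += dt / 2.0
        return c * w
    raise ValueError(f"unknown quadrature {quadrature!r}")


def trim_trailing_baseline(
    series: TracerSeries, baseline: float = 0.0, eps: float = TRIM_EPS
) -> TracerSeries:
    """Drop trailing samples indistinguishable from the baseline.

    Mirrors stopping collection once no tracer color remains; one sample at
    the baseline is kept so the curve returns to zero.
    """
    c = series.concentrations
    above = np.nonzero(c > baseline + eps)[0]
    if above.size == 0:
        raise UnnormalizableSeriesError("entire series is at baseline")
    last = min(int(above[-1]) + 1, c.size - 1)
    if last == c.size - 1:
        return series
    return TracerSeries(series.times[: last + 1], c[: last + 1], series.run_label)


def normalize_to_E(
    series: TracerSeries,
    baseline: float = 0.0,
    quadrature: Quadrature = "segment",
) -> RTDCurves:
    """Exit-age density: E_i = C_i / sum_j C_j dt_j, so sum E_i dt_i = 1."""
    c = _effective_concentration(series, baseline)
    total = _weights(series, baseline, quadrature).sum()
    if total <= 0:
        raise UnnormalizableSeriesError("signal has no mass after baseline subtraction")
    return RTDCurves(times=series.times.copy(), E=c / total)


def cumulative_F(curves: RTDCurves, quadrature: Quadrature = "segment") -> RTDCurves:
    """F_i = sum_{j<=i} E_j dt_j (running fraction of tracer that has exited)."""
    if quadrature == "segment":
        contrib = curves.E * segment_widths(curves.times)
        F = np.cumsum(contrib)
    else:
        dt = np.diff(curves.times)
        steps = dt * (curves.E[:-1] + curves.E[1:]) / 2.0
        F = np.concatenate([[0.0], np.cumsum(steps)])
    curves.F = F
    return curves


def mean_residence_time(
    series: TracerSeries,
    baseline: float = 0.0,
    quadrature: Quadrature = "segment",
) -> float:
    """First moment: MRT = sum C_i t_i dt_i / sum C_i dt_i."""
    w = _weights(series, baseline, quadrature)
    total = w.sum()
    if total <= 0:
        raise UnnormalizableSeriesError("signal has no mass after baseline subtraction")
    return float((w * series.times).sum() / total)


def rtd_variance(
    series: TracerSeries,
    mrt: float,
    baseline: float = 0.0,
    quadrature: Quadrature = "segment",
) -> float:
    """Second central moment: sum C_i t_i^2 dt_i / sum C_i dt_i - MRT^2."""
    w = _weights(series, baseline, quadrature)
    total = w.sum()
    if total <= 0:
        raise UnnormalizableSeriesError("signal has no mass after baseline subtraction")
    second = float((w * series.times**2).sum() / total)
    var = second - mrt**2
    if var < -1e-9 * max(1.0, mrt**2):
        raise NumericalInconsistencyError(f"negative variance {var}")
    return max(var, 0.0)


def dimensionless(curves: RTDCurves, mrt: float) -> RTDCurves:
    """theta = t/MRT, E(theta) = MRT*E(t), F(theta) = F(t)."""
    if mrt <= 0:
        raise ValueError("mrt must be positive")
    curves.theta = curves.times / mrt
    curves.E_theta = mrt * curves.E
    if curves.F is not None:
        curves.F_theta = curves.F.copy()
    return curves


def peclet_forward(pe: float) -> float:
    """Closed-vessel dispersion relation: sigma_theta^2 as a function of Pe.

    Strictly decreasing on (0, inf); -> 1 as Pe -> 0+, -> 0 as Pe -> inf.
    """
    if pe <= 0:
        raise PecletDomainError("Pe must be positive")
    if pe < 1e-4:
        # series expansion avoids catastrophic cancellation near 0
        return 1.0 - pe / 3.0 + pe**2 / 12.0 - pe**3 / 60.0
    return 2.0 / pe - (2.0 / pe**2) * (1.0 - math.exp(-pe))


def solve_peclet(
    sigma_theta2: float,
    bracket: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-12,
) -> float:
    """Invert the closed-vessel relation by bracketed root finding.

    Raises PecletDomainError outside (0, 1), where no positive root exists.
    """
    if not (0.0 < sigma_theta2 < 1.0):
        raise PecletDomainError(
            f"sigma_theta^2 = {sigma_theta2:g} outside (0, 1); "
            "flow is more dispersed than a single ideal mixer"
            if sigma_theta2 >= 1.0
            else f"sigma_theta^2 = {sigma_theta2:g} must be positive"
        )
    lo, hi = bracket

    def residual(pe: float) -> float:
        return peclet_forward(pe) - sigma_theta2

    # expand until the root is bracketed (residual decreasing in pe)
    while residual(lo) < 0 and lo > 1e-300:
        lo /= 10.0
    while residual(hi) > 0 and hi < 1e300:
        hi *= 10.0
    pe = brentq(residual, lo, hi, xtol=tol, rtol=8.9e-16, maxiter=200)
    if abs(peclet_forward(pe) - sigma_theta2) > 1e-10:
        raise NumericalInconsistencyError("root residual exceeds 1e-10")
    return float(pe)


def analyze_run(
    series: TracerSeries,
    baseline: float = 0.0,
    quadrature: Quadrature = "segment",
    trim: bool = False,
) -> RTDSummary:
    """Full pipeline: E, F, MRT, variance, dimensionless curves, Peclet."""
    if trim:
        series = trim_trailing_baseline(series, baseline)
    curves = normalize_to_E(series, baseline, quadrature)
    curves = cumulative_F(curves, quadrature)
    mrt = mean_residence_time(series, baseline, quadrature)
    var = rtd_variance(series, mrt, baseline, quadrature)
    curves = dimensionless(curves, mrt)
    sigma_theta2 = var / mrt**2
    try:
        pe = solve_peclet(sigma_theta2)
        solvable = True
    except PecletDomainError:
        pe = None
        solvable = False
    return RTDSummary(
        mrt=mrt,
        variance=var,
        sigma_theta2=sigma_theta2,
        peclet=pe,
        peclet_solvable=solvable,
        curves=curves,
        run_label=series.run_label,
    )


def relative_change(before: float, after: float) -> float:
    """Percent reduction 100*(before - after)/before."""
    if before <= 0:
        raise ValueError("before must be positive")
    return 100.0 * (before - after) / before
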