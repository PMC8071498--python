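"""Linear calibration of saturation against arginine concentration.

Classical calibration: mean tinted saturation (the response) is regressed
on known standard concentrations by ordinary least squares, and unknown
concentrations are obtained by inverting the fitted line,
``C = (S - intercept) / slope``.  The response axis is saturation because
that is how standard curves for this assay are plotted and because the
concentration is the error-free design variable of the standard series.

A healthy assay has a strictly positive slope; a zero or negative slope
means the color response did not develop and inversion is meaningless, so
fitting raises :class:`NonResponsiveAssayError` in that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .color import ColorMetrics

__all__ = [
    "NonResponsiveAssayError",
    "StandardSeries",
    "CalibrationModel",
    "ConcentrationEstimate",
    "fit_calibration",
    "invert",
    "series_from_measurements",
]


class NonResponsiveAssayError(RuntimeError):
    """Fitted slope is not positive: the assay showed no color response."""


@dataclass(frozen=True)
class StandardSeries:
    """Measured standard series: (concentration µM, ColorMetrics) pairs."""

    points: tuple[tuple[float, ColorMetrics], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a standard series needs at least 2 points")
        concs = self.concentrations
        if np.any(concs < 0):
            raise ValueError("standard concentrations must be >= 0")
        if np.unique(concs).size < 2:
            raise ValueError("at least 2 distinct concentrations required")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def saturations(self) -> np.ndarray:
        return np.array([m.mean_saturation for _, m in self.points], dtype=float)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted standard curve S = intercept + slope * C.

    ``saturation_span`` records the (min, max) of the fitted standards'
    measured saturations; inverse predictions outside it are flagged as
    extrapolations.  ``residual_sd`` uses n - 2 degrees of freedom and is 0
    for a two-point fit.
    """

    slope: float  # % saturation per µM
    intercept: float  # % saturation at 0 µM
    r_squared: float
    n_points: int
    residual_sd: float
    saturation_span: tuple[float, float] = field(default=(-np.inf, np.inf))

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict_saturation(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse prediction for one sample.

    ``in_range`` is False when the observed saturation lies outside the
    span of the standards (extrapolation) or the raw estimate was negative
    and clamped to 0.
    """

    value: float  # µM
    in_range: bool
    saturation_used: float  # %


def fit_calibration(series: StandardSeries) -> CalibrationModel:
    """Ordinary least squares of mean saturation on concentration.

    Raises
    ------
    NonResponsiveAssayError
        If the fitted slope is <= 0.
    """
    conc = series.concentrations
    sat = series.saturations
    n = conc.size

    result = stats.linregress(conc, sat)
    slope = float(result.slope)
    intercept = float(result.intercept)
    if slope <= 0:
        raise NonResponsiveAssayError(
            f"calibration slope {slope:.4g} %/µM is not positive"
        )

    residuals = sat - (intercept + slope * conc)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((sat - sat.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else 0.0

    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r_squared, 0.0), 1.0),
        n_points=n,
        residual_sd=residual_sd,
        saturation_span=(float(sat.min()), float(sat.max())),
    )


def invert(model: CalibrationModel, saturation: float) -> ConcentrationEstimate:
    """Invert the standard curve at an observed saturation.

    Negative raw estimates (saturation below the intercept) are clamped to
    0 µM and marked out of range.
    """
    if model.slope <= 0:
        raise NonResponsiveAssayError("cannot invert a non-positive slope")
    raw = (saturation - model.intercept) / model.slope
    lo, hi = model.saturation_span
    in_range = bool(lo <= saturation <= hi)
    if raw < 0:
        return ConcentrationEstimate(value=0.0, in_range=False, saturation_used=saturation)
    return ConcentrationEstimate(value=float(raw), in_range=in_range, saturation_used=saturation)


def series_from_measurements(
    concentrations: Sequence[float], metrics: Sequence[ColorMetrics]
) -> StandardSeries:
    """Pair concentrations with measured metrics into a StandardSeries."""
    if len(concentrations) != len(metrics):
        raise ValueError("lengths differ")
    return StandardSeries(points=tuple(zip(map(float, concentrations), metrics)))
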