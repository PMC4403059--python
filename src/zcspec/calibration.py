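"""Single-wavelength calibration: OLS fits, replicate-curve summaries, LOD/LOQ.

A calibration curve regresses the derivative amplitude measured at the
analyte's working wavelength on the standard concentration (µg/mL).  Method
validation repeats the curve several times (six series in the classical
design); the across-curve mean, SD, RSD% and confidence interval of slope
and intercept summarise the method's linearity, and the detection limits
follow the ICH convention LOD = 3.3σ/s, LOQ = 10σ/s with σ the SD of the
intercept and s the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "CalibrationSummary",
    "ConcentrationEstimate",
    "FitError",
    "AggregationError",
    "fit_calibration",
    "summarize_curves",
    "lod_loq",
    "predict_concentration",
]


class FitError(ValueError):
    """Calibration data unsuitable for regression."""


class AggregationError(ValueError):
    """Curves cannot be pooled into one summary."""


@dataclass(frozen=True)
class CalibrationCurve:
    """One OLS calibration line with its regression statistics."""

    analyte_id: str
    wavelength: float
    order: int
    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r: float
    sd_slope: float
    sd_intercept: float

    @property
    def linear_range(self) -> tuple[float, float]:
        return float(self.concentrations.min()), float(self.concentrations.max())

    def equation(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return f"Y = {self.slope:.5g}·X {sign} {abs(self.intercept):.5g}"


@dataclass(frozen=True)
class CalibrationSummary:
    """Across-curve aggregate statistics for one analyte/wavelength.

    ``ci_slope``/``ci_intercept`` are half-widths of the 95% confidence
    interval of the mean, ``z · SD/√n`` with z = 1.96 by default (Student's t
    available via ``summarize_curves(use_t=True)``).
    """

    analyte_id: str
    wavelength: float
    order: int
    n_curves: int
    slope_mean: float
    slope_sd: float
    slope_rsd_percent: float
    ci_slope: float
    intercept_mean: float
    intercept_sd: float
    ci_intercept: float
    r: float
    linear_range: tuple[float, float]
    lod: float
    loq: float

    @property
    def slope(self) -> float:
        return self.slope_mean

    @property
    def intercept(self) -> float:
        return self.intercept_mean

    def equation(self) -> str:
        sign = "+" if self.intercept_mean >= 0 else "-"
        return f"Y = {self.slope_mean:.5g}·X {sign} {abs(self.intercept_mean):.5g}"


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse-regression concentration with a linear-range flag."""

    value: float
    in_range: bool

    def __float__(self) -> float:
        return self.value


def fit_calibration(
    concentrations: Sequence[float],
    responses: Sequence[float],
    analyte_id: str = "",
    wavelength: float = float("nan"),
    order: int = 0,
) -> CalibrationCurve:
    """Ordinary least squares of response on concentration.

    Requires at least three points with non-degenerate concentrations;
    reports the correlation coefficient and the standard errors of slope
    and intercept.
    """
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if x.size != y.size or x.size < 3:
        raise FitError("need at least 3 matched (concentration, response) points")
    if np.any(x < 0):
        raise FitError("concentrations must be non-negative")
    if np.ptp(x) == 0:
        raise FitError("concentrations are all equal; slope is undefined")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte_id=analyte_id,
        wavelength=wavelength,
        order=order,
        concentrations=x,
        responses=y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        sd_slope=float(res.stderr),
        sd_intercept=float(res.intercept_stderr),
    )


def lod_loq(sd_intercept: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits (µg/mL): 3.3σ/s and 10σ/s.

    σ is the standard deviation of the calibration intercept, s the slope.
    Rounding for reporting happens downstream, never here.
    """
    if slope <= 0:
        raise ValueError("slope must be positive for LOD/LOQ")
    if sd_intercept < 0:
        raise ValueError("sd_intercept must be non-negative")
    return 3.3 * sd_intercept / slope, 10.0 * sd_intercept / slope


def summarize_curves(
    curves: Sequence[CalibrationCurve],
    z: float = 1.96,
    use_t: bool = False,
) -> CalibrationSummary:
    """Aggregate replicate calibration curves of the same analyte.

    Slope and intercept are summarised by their across-curve mean, sample SD
    (n−1), RSD% and a 95% CI half-width z·SD/√n.  LOD/LOQ use the
    across-curve SD of the intercept and the mean slope.
    """
    if len(curves) < 2:
        raise AggregationError("need at least two curves to summarise")
    ids = {c.analyte_id for c in curves}
    wls = {round(c.wavelength, 6) for c in curves if not np.isnan(c.wavelength)}
    if len(ids) > 1 or len(wls) > 1:
        raise AggregationError(f"mixed analytes/wavelengths in summary: {ids}, {wls}")
    n = len(curves)
    slopes = np.array([c.slope for c in curves])
    intercepts = np.array([c.intercept for c in curves])
    factor = float(stats.t.ppf(0.975, n - 1)) if use_t else z
    slope_sd = float(slopes.std(ddof=1))
    intercept_sd = float(intercepts.std(ddof=1))
    slope_mean = float(slopes.mean())
    # derivative amplitudes may be negative; detection limits use |slope|
    lod, loq = lod_loq(intercept_sd, abs(slope_mean)) if slope_mean != 0 else (float("nan"),) * 2
    lo = min(c.linear_range[0] for c in curves)
    hi = max(c.linear_range[1] for c in curves)
    return CalibrationSummary(
        analyte_id=curves[0].analyte_id,
        wavelength=curves[0].wavelength,
        order=curves[0].order,
        n_curves=n,
        slope_mean=slope_mean,
        slope_sd=slope_sd,
        slope_rsd_percent=100.0 * slope_sd / abs(slope_mean) if slope_mean != 0 else float("inf"),
        ci_slope=factor * slope_sd / np.sqrt(n),
        intercept_mean=float(intercepts.mean()),
        intercept_sd=intercept_sd,
        ci_intercept=factor * intercept_sd / np.sqrt(n),
        r=float(np.mean([c.r for c in curves])),
        linear_range=(lo, hi),
        lod=float(lod),
        loq=float(loq),
    )


def predict_concentration(
    curve: CalibrationCurve | CalibrationSummary, response: float
) -> ConcentrationEstimate:
    """Inverse regression: concentration = (response − intercept)/slope.

    The estimate is flagged ``in_range=False`` when it falls outside the
    calibration's linear range (boundaries included).
    """
    slope = curve.slope
    if slope == 0:
        raise ValueError("slope is zero; concentration is undefined")
    value = (response - curve.intercept) / slope
    lo, hi = curve.linear_range
    eps = 1e-9 * max(1.0, abs(hi))
    return ConcentrationEstimate(value=float(value), in_range=bool(lo - eps <= value <= hi + eps))
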