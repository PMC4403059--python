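"""Spectra and derivative spectra.

A :class:`Spectrum` is an absorbance trace on a strictly increasing, uniform
wavelength grid (nm, AU).  Derivative spectra of order 1-4 are formed either
by iterated centered differencing over a peak-to-peak width ``delta_lambda``
(the classic instrument-style Δλ derivative) or by a Savitzky-Golay
polynomial filter whose window approximates the same width.

Derivatives are undefined where the differencing window leaves the grid; the
returned trace covers only the interior.  No padding is applied, because
padded edges manufacture spurious zero-crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

__all__ = [
    "Spectrum",
    "DerivativeConfig",
    "DerivativeSpectrum",
    "SpectrumError",
    "RangeError",
    "ConfigError",
    "resample",
    "derivative",
    "derivative_noise_sd",
    "uniform_grid",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
]

_UNIFORM_TOL = 1e-9


class SpectrumError(ValueError):
    """Invalid spectral data."""


class RangeError(SpectrumError):
    """Requested wavelength range not covered by the source spectrum."""


class ConfigError(SpectrumError):
    """Derivative configuration incompatible with the spectrum's grid."""


def uniform_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Uniform wavelength grid from ``start`` to ``stop`` inclusive."""
    n = int(round((stop - start) / step))
    if n < 2:
        raise SpectrumError("grid must contain at least 3 points")
    return start + step * np.arange(n + 1)


@dataclass(frozen=True)
class Spectrum:
    """Absorbance vs wavelength on a uniform grid.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing and uniform
    absorbance : array, AU, same length, all finite
    meta : free-form provenance (sample id, true concentrations, dilution)
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.size < 3:
            raise SpectrumError("need a 1-D grid with at least 3 points")
        if ab.shape != wl.shape:
            raise SpectrumError("wavelengths and absorbance lengths differ")
        steps = np.diff(wl)
        if steps.min() <= 0:
            raise SpectrumError("wavelengths must be strictly increasing")
        if steps.max() - steps.min() > _UNIFORM_TOL:
            raise SpectrumError("wavelength grid must be uniform to 1e-9 nm")
        if not np.all(np.isfinite(ab)):
            raise SpectrumError("absorbance must be finite everywhere")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    @property
    def step(self) -> float:
        return float((self.wavelengths[-1] - self.wavelengths[0]) / (self.wavelengths.size - 1))

    def __len__(self) -> int:
        return self.wavelengths.size

    def value_at(self, wavelength: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of absorbance at ``wavelength`` (must lie in range)."""
        w = np.asarray(wavelength, dtype=float)
        if np.any(w < self.wavelengths[0] - _UNIFORM_TOL) or np.any(
            w > self.wavelengths[-1] + _UNIFORM_TOL
        ):
            raise RangeError("wavelength outside the spectrum's range")
        return np.interp(w, self.wavelengths, self.absorbance)


@dataclass(frozen=True)
class DerivativeConfig:
    """Settings for forming a derivative spectrum.

    ``delta_lambda`` is the peak-to-peak differencing width in nm.  For the
    finite-difference method it is rounded to the nearest even number of grid
    steps when applied (the effective width is recorded on the result); for
    Savitzky-Golay it sets the filter window (odd point count closest to
    Δλ/step) and ``sg_polyorder`` must exceed ``order``.
    """

    order: int
    delta_lambda: float
    method: str = "finite_difference"
    sg_polyorder: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.order) <= 4:
            raise ConfigError("derivative order must be between 1 and 4")
        if not self.delta_lambda > 0:
            raise ConfigError("delta_lambda must be positive")
        if self.method not in ("finite_difference", "savitzky_golay"):
            raise ConfigError(f"unknown derivative method {self.method!r}")
        if self.method == "savitzky_golay":
            if self.sg_polyorder is None or self.sg_polyorder <= self.order:
                raise ConfigError("sg_polyorder must exceed the derivative order")


@dataclass(frozen=True)
class DerivativeSpectrum:
    """n-th order derivative trace (AU·nm⁻ⁿ) with its provenance.

    ``effective_delta_lambda`` is the width actually realised on the grid
    (rounding of Δλ to grid steps); ``source`` is the parent spectrum.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    config: DerivativeConfig
    effective_delta_lambda: float
    source: Spectrum | None = None

    @property
    def step(self) -> float:
        return float((self.wavelengths[-1] - self.wavelengths[0]) / (self.wavelengths.size - 1))

    def __len__(self) -> int:
        return self.wavelengths.size

    def value_at(self, wavelength: float | np.ndarray) -> np.ndarray:
        w = np.asarray(wavelength, dtype=float)
        if np.any(w < self.wavelengths[0] - _UNIFORM_TOL) or np.any(
            w > self.wavelengths[-1] + _UNIFORM_TOL
        ):
            raise RangeError("wavelength outside the derivative's domain")
        return np.interp(w, self.wavelengths, self.values)


def resample(spectrum: Spectrum, grid_start: float, grid_stop: float, step: float) -> Spectrum:
    """Linearly interpolate ``spectrum`` onto a new uniform grid.

    The requested range must lie inside the source range; ``meta`` is carried
    over unchanged.
    """
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid_start < lo - _UNIFORM_TOL or grid_stop > hi + _UNIFORM_TOL:
        raise RangeError(
            f"requested range [{grid_start}, {grid_stop}] outside source range [{lo}, {hi}]"
        )
    grid = uniform_grid(grid_start, grid_stop, step)
    values = np.interp(grid, spectrum.wavelengths, spectrum.absorbance)
    return Spectrum(grid, values, meta=dict(spectrum.meta))


def _fd_half_window(delta_lambda: float, step: float) -> int:
    half = int(round(delta_lambda / (2.0 * step)))
    if half < 1:
        raise ConfigError("delta_lambda must span at least 2 grid steps")
    return half


def derivative(spectrum: Spectrum, config: DerivativeConfig) -> DerivativeSpectrum:
    """Compute the order-n derivative of ``spectrum`` under ``config``.

    finite_difference: order 1 is the centered difference
    ``D(λ) = [A(λ+Δλ/2) − A(λ−Δλ/2)] / Δλ`` with Δλ rounded to the nearest
    even number of grid steps; higher orders apply the operator iteratively,
    shrinking the domain by Δλ/2 per application on each side.

    savitzky_golay: a polynomial least-squares filter of window width equal
    to the odd point count closest to Δλ/step, differentiated ``order``
    times, with the result scaled by step⁻ⁿ so units are AU·nm⁻ⁿ.
    """
    step = spectrum.step
    if config.method == "finite_difference":
        half = _fd_half_window(config.delta_lambda, step)
        m = 2 * half
        eff = m * step
        if spectrum.wavelengths.size - config.order * m < 2:
            raise ConfigError("differencing window wider than the spectrum")
        vals = spectrum.absorbance
        for _ in range(config.order):
            vals = (vals[m:] - vals[:-m]) / eff
        k = config.order * half
        wl = spectrum.wavelengths[k:-k]
    else:
        w = int(round(config.delta_lambda / step))
        if w % 2 == 0:
            w += 1
        w = max(w, config.sg_polyorder + 1 + ((config.sg_polyorder + 1) % 2 == 0))
        if w % 2 == 0:
            w += 1
        if w > spectrum.wavelengths.size - 2:
            raise ConfigError("Savitzky-Golay window wider than the spectrum")
        if w < 3:
            raise ConfigError("delta_lambda must span at least 2 grid steps")
        hw = (w - 1) // 2
        smoothed = savgol_filter(
            spectrum.absorbance, w, config.sg_polyorder, deriv=config.order, delta=step
        )
        vals = smoothed[hw:-hw]
        wl = spectrum.wavelengths[hw:-hw]
        eff = (w - 1) * step
    return DerivativeSpectrum(
        wavelengths=wl,
        values=vals,
        config=config,
        effective_delta_lambda=float(eff),
        source=spectrum,
    )


def derivative_noise_sd(config: DerivativeConfig, step: float, noise_sd: float) -> float:
    """SD of the derivative trace induced by i.i.d. Gaussian noise of ``noise_sd`` AU.

    For iterated centered differencing the n-fold operator has binomial
    weights, so the variance gain is C(2n, n)/Δλ_eff^{2n}; for Savitzky-Golay
    it is the squared norm of the filter coefficients.
    """
    if config.method == "finite_difference":
        half = _fd_half_window(config.delta_lambda, step)
        eff = 2 * half * step
        from math import comb

        return float(noise_sd * np.sqrt(comb(2 * config.order, config.order)) / eff**config.order)
    w = int(round(config.delta_lambda / step))
    if w % 2 == 0:
        w += 1
    w = max(w, config.sg_polyorder + 2)
    if w % 2 == 0:
        w += 1
    coeffs = savgol_coeffs(w, config.sg_polyorder, deriv=config.order, delta=step)
    return float(noise_sd * np.linalg.norm(coeffs))


# ---------------------------------------------------------------------------
# File formats


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column spectrum CSV (``wavelength_nm,absorbance``).

    Lines starting with ``#`` are treated as comments.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "wavelength_nm" not in cols or "absorbance" not in cols:
        raise SpectrumError("expected columns wavelength_nm,absorbance")
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy())


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader for AFFN ``##XYDATA=(X++(Y..Y))`` blocks.

    Honours XFACTOR/YFACTOR; compressed (SQZ/DIF/DUP) encodings are not
    supported.
    """
    xfactor = yfactor = 1.0
    lines: list[tuple[float, list[float]]] = []  # (line start x, y values)
    in_xy = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XFACTOR":
                    xfactor = float(val)
                elif key == "YFACTOR":
                    yfactor = float(val)
                elif key == "XYDATA":
                    in_xy = True
                elif in_xy:
                    in_xy = False
                continue
            if in_xy:
                vals = [float(p) for p in line.replace(",", " ").split()]
                lines.append((vals[0] * xfactor, [v * yfactor for v in vals[1:]]))
    npts = sum(len(ys) for _, ys in lines)
    if npts < 3:
        raise SpectrumError("no XYDATA table found")
    xs: list[float] = []
    ys_all: list[float] = []
    for i, (x0, yv) in enumerate(lines):
        if len(yv) > 1:
            if i + 1 < len(lines):
                dx = (lines[i + 1][0] - x0) / len(yv)
            else:  # last line: reuse the spacing of the previous block
                dx = (x0 - lines[i - 1][0]) / len(lines[i - 1][1]) if i > 0 else 1.0
        else:
            dx = 0.0
        for j, y in enumerate(yv):
            xs.append(x0 + j * dx)
            ys_all.append(y)
    x = np.asarray(xs)
    y = np.asarray(ys_all)
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    # instrument tables may carry slightly ragged abscissae; re-grid uniformly
    grid = np.linspace(x[0], x[-1], x.size)
    return Spectrum(grid, np.interp(grid, x, y))
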