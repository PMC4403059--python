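"""Zero-crossing location and working-wavelength selection.

The zero-crossing technique quantifies one analyte of an overlapped mixture
at a wavelength where the derivative spectra of the *other* compounds pass
through zero: by Beer-Lambert additivity and the linearity of the derivative
operator, the mixture derivative there depends on the analyte alone.

This module finds crossings of derivative traces, intersects crossing sets
of two interferents, and automates the selection of a working wavelength by
scoring every grid wavelength on analyte signal times calibration linearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import ConfigError, DerivativeConfig, DerivativeSpectrum

__all__ = [
    "CrossingSet",
    "WorkingWavelength",
    "SelectionError",
    "find_zero_crossings",
    "common_zero_crossings",
    "select_working_wavelength",
]


class SelectionError(RuntimeError):
    """No wavelength satisfies the interference-rejection tolerance."""


@dataclass(frozen=True)
class CrossingSet:
    """Zero crossings of one compound's derivative trace.

    ``crossings`` are ascending wavelengths (nm); ``slope_signs`` is +1 where
    the trace crosses upward, -1 downward, 0 for a tangent touch on an exact
    zero run.
    """

    compound_id: str
    crossings: np.ndarray
    slope_signs: np.ndarray
    config: DerivativeConfig

    def __len__(self) -> int:
        return self.crossings.size

    def __iter__(self):
        return iter(zip(self.crossings, self.slope_signs))


@dataclass(frozen=True)
class WorkingWavelength:
    """Selected (order, Δλ, λ) triple for quantifying one analyte.

    ``interferent_residual`` is the largest interferent derivative magnitude
    at the selected wavelength (AU·nm⁻ⁿ, at the interferents' working
    concentrations); ``analyte_signal`` is the analyte's own derivative value
    there.
    """

    analyte_id: str
    wavelength: float
    order: int
    delta_lambda: float
    interferent_residual: float
    analyte_signal: float
    score: float = 0.0
    config: DerivativeConfig | None = None


def find_zero_crossings(
    dspec: DerivativeSpectrum,
    amplitude_floor: float = 0.0,
    compound_id: str = "",
) -> CrossingSet:
    """Locate every zero crossing of a derivative trace.

    Sign changes between adjacent grid points are placed by linear
    interpolation; runs of exact zeros collapse to their midpoint.  Crossings
    whose flanking amplitudes are both below ``amplitude_floor`` are dropped
    (noise guard).  An empty crossing set is a valid result.
    """
    v = dspec.values
    wl = dspec.wavelengths
    s = np.sign(v)
    out_wl: list[float] = []
    out_sign: list[int] = []
    i = 0
    n = v.size
    while i < n - 1:
        if s[i] == 0:
            j = i
            while j < n and s[j] == 0:
                j += 1
            # run of exact zeros v[i..j-1]; interior runs collapse to midpoint
            if i > 0 and j < n:
                left, right = v[i - 1], v[j]
                if max(abs(left), abs(right)) >= amplitude_floor:
                    out_wl.append(0.5 * (wl[i] + wl[j - 1]))
                    out_sign.append(int(np.sign(right) if np.sign(right) != np.sign(left) else 0))
            i = j
            continue
        if s[i] * s[i + 1] < 0:
            if max(abs(v[i]), abs(v[i + 1])) >= amplitude_floor:
                lam = wl[i] + (wl[i + 1] - wl[i]) * v[i] / (v[i] - v[i + 1])
                out_wl.append(float(lam))
                out_sign.append(int(s[i + 1]))
        i += 1
    return CrossingSet(
        compound_id=compound_id,
        crossings=np.asarray(out_wl),
        slope_signs=np.asarray(out_sign, dtype=int),
        config=dspec.config,
    )


def common_zero_crossings(a: CrossingSet, b: CrossingSet, wavelength_tol: float) -> np.ndarray:
    """Wavelengths where both compounds' derivatives vanish.

    Returns midpoints of crossing pairs lying within ``wavelength_tol`` of
    each other, merged so that no two reported wavelengths are closer than
    the tolerance.  Both sets must come from the same derivative config.
    """
    if a.config != b.config:
        raise ConfigError("crossing sets were computed under different derivative configs")
    if len(a) == 0 or len(b) == 0:
        return np.empty(0)
    bx = np.sort(b.crossings)
    mids: list[float] = []
    for lam in a.crossings:
        lo = np.searchsorted(bx, lam - wavelength_tol)
        hi = np.searchsorted(bx, lam + wavelength_tol, side="right")
        for mu in bx[lo:hi]:
            mids.append(0.5 * (lam + mu))
    if not mids:
        return np.empty(0)
    mids_arr = np.sort(np.asarray(mids))
    merged = [mids_arr[0]]
    for m in mids_arr[1:]:
        if m - merged[-1] <= wavelength_tol:
            merged[-1] = 0.5 * (merged[-1] + m)
        else:
            merged.append(m)
    return np.asarray(merged)


def _check_common_grid(specs: Sequence[DerivativeSpectrum]) -> None:
    ref = specs[0]
    for d in specs[1:]:
        if d.config != ref.config or d.wavelengths.size != ref.wavelengths.size or not np.allclose(
            d.wavelengths, ref.wavelengths, atol=1e-9
        ):
            raise ConfigError("derivative spectra do not share a grid and config")


def select_working_wavelength(
    analyte: DerivativeSpectrum,
    interferents: Sequence[DerivativeSpectrum],
    calibration_stack: Sequence[DerivativeSpectrum],
    concentrations: Sequence[float],
    residual_tol: float | None = None,
    relative_tol: float = 0.005,
    analyte_id: str = "",
) -> WorkingWavelength:
    """Pick the wavelength that quantifies the analyte free of interference.

    Candidate wavelengths are those where every interferent's |D| is at or
    below its tolerance: ``residual_tol`` in absolute units if given,
    otherwise ``relative_tol`` times that interferent's own maximum |D| (at
    the concentration it was simulated/measured at).  Among candidates the
    score is |analyte D| times the squared Pearson correlation of the
    mixture derivative with the analyte concentration across the calibration
    stack; ties break toward larger |analyte D|, then lower wavelength.
    """
    specs = [analyte, *interferents, *calibration_stack]
    _check_common_grid(specs)
    a = np.abs(analyte.values)
    if a.max() == 0.0:
        raise SelectionError(f"analyte {analyte_id!r} has an identically zero derivative")
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size != len(calibration_stack):
        raise ValueError("one concentration per calibration spectrum required")

    mask = np.ones(a.size, dtype=bool)
    norm_resid = np.zeros(a.size)
    for d in interferents:
        mag = np.abs(d.values)
        peak = mag.max()
        tol = residual_tol if residual_tol is not None else relative_tol * peak
        if peak == 0.0:
            continue
        mask &= mag <= tol
        norm_resid = np.maximum(norm_resid, mag / peak)
    if not mask.any():
        k = int(np.argmin(norm_resid))
        raise SelectionError(
            "no wavelength rejects all interferents; best combined residual "
            f"{norm_resid[k]:.3%} of interferent maximum at {analyte.wavelengths[k]:.1f} nm"
        )

    M = np.stack([d.values for d in calibration_stack])  # (n_cal, n_wl)
    c0 = conc - conc.mean()
    M0 = M - M.mean(axis=0)
    num = c0 @ M0
    den = np.sqrt((c0**2).sum() * (M0**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, (num / np.where(den == 0, 1.0, den)) ** 2, 0.0)
    score = np.where(mask, a * r2, -np.inf)

    best = score.max()
    tied = np.flatnonzero(score >= best * (1 - 1e-12) if best > 0 else score == best)
    tied = tied[np.argsort(-a[tied], kind="stable")]
    amax = a[tied[0]]
    tied = tied[a[tied] >= amax * (1 - 1e-12)]
    k = int(tied[np.argmin(analyte.wavelengths[tied])])

    resid = 0.0
    for d in interferents:
        resid = max(resid, float(abs(d.values[k])))
    return WorkingWavelength(
        analyte_id=analyte_id,
        wavelength=float(analyte.wavelengths[k]),
        order=analyte.config.order,
        delta_lambda=analyte.effective_delta_lambda,
        interferent_residual=resid,
        analyte_signal=float(analyte.values[k]),
        score=float(score[k]),
        config=analyte.config,
    )
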