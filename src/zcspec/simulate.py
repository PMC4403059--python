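"""Synthetic three-compound UV spectra under Beer-Lambert mixing.

Emulates the chemical system of the cold-formulation assay — one dominant
absorber (acetaminophen, 25 µg/mL working level) and two minor absorbers
(diphenhydramine and pseudoephedrine hydrochloride, ~1.5 µg/mL) with heavily
overlapped bands in 200–300 nm — so the derivative/zero-crossing machinery
can be exercised end to end without instrument data.

Band positions and absorptivities are SYNTHETIC: they qualitatively mimic the
published zero-order traces (a dominant mid-UV acetaminophen band, a strong
short-wavelength diphenhydramine band with weak benzenoid structure, and a
weak structured benzenoid absorption plus end absorption for
pseudoephedrine), but are not calibrated to the real drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra import Spectrum, uniform_grid

__all__ = [
    "GaussianBand",
    "CompoundSpectralModel",
    "MixtureSpec",
    "CalibrationDesign",
    "compound_spectrum",
    "mixture_spectrum",
    "generate_calibration_dataset",
    "default_models",
    "default_designs",
    "default_grid",
    "DEFAULT_NOISE_SD",
    "TABLET_LABEL_MG",
]

DEFAULT_NOISE_SD = 0.002  # AU, homoscedastic instrument noise
TABLET_LABEL_MG = {"acetaminophen": 500.0, "diphenhydramine": 25.0, "pseudoephedrine": 30.0}


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: ε(λ) = epsilon_peak·exp(−(λ−center)²/2σ²)."""

    center: float  # nm
    sigma: float  # nm
    epsilon_peak: float  # AU·mL·µg⁻¹·cm⁻¹


@dataclass(frozen=True)
class CompoundSpectralModel:
    """Sum-of-Gaussian-bands absorptivity model for one compound."""

    compound_id: str
    bands: tuple[GaussianBand, ...]
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ValueError("a compound model needs at least one band")
        if any(b.sigma <= 0 or b.epsilon_peak < 0 for b in self.bands):
            raise ValueError("bands need positive sigma and non-negative epsilon")

    def epsilon(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for b in self.bands:
            out += b.epsilon_peak * np.exp(-((wl - b.center) ** 2) / (2.0 * b.sigma**2))
        return out


@dataclass(frozen=True)
class MixtureSpec:
    """Concentrations (µg/mL), noise level (AU) and seed for one mixture."""

    concentrations: Mapping[str, float]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CalibrationDesign:
    """Analyte dilution series with the other compounds held fixed."""

    analyte_id: str
    levels: tuple[float, ...]  # µg/mL
    fixed_levels: Mapping[str, float] = field(default_factory=dict)


def default_grid() -> np.ndarray:
    """The recorded range of the method: 200–300 nm at 0.1 nm."""
    return uniform_grid(200.0, 300.0, 0.1)


def compound_spectrum(
    model: CompoundSpectralModel, conc: float, grid: np.ndarray | None = None
) -> Spectrum:
    """Noiseless Beer-Lambert spectrum A(λ) = ε(λ)·c·l of one compound."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    a = model.epsilon(wl) * conc * model.path_length
    return Spectrum(wl, a, meta={"compound_id": model.compound_id, "conc_ug_per_ml": conc})


def mixture_spectrum(
    models: Sequence[CompoundSpectralModel],
    spec: MixtureSpec,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Additive mixture of component spectra plus i.i.d. Gaussian noise.

    The true concentrations are stored in ``meta["concentrations"]``; the
    noise stream is fully determined by ``spec.seed``.
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    by_id = {m.compound_id: m for m in models}
    a = np.zeros_like(wl)
    for cid, conc in spec.concentrations.items():
        if cid not in by_id:
            raise KeyError(f"no spectral model for compound {cid!r}")
        a += by_id[cid].epsilon(wl) * conc * by_id[cid].path_length
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a = a + rng.normal(0.0, spec.noise_sd, size=wl.size)
    return Spectrum(
        wl,
        a,
        meta={"concentrations": dict(spec.concentrations), "noise_sd": spec.noise_sd, "seed": spec.seed},
    )


def generate_calibration_dataset(
    models: Sequence[CompoundSpectralModel],
    design: CalibrationDesign,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> list[Spectrum]:
    """One mixture spectrum per design level, truth recorded in ``meta``.

    Reproducible: the i-th spectrum's noise stream is seeded from
    (seed, i) via numpy's seed-sequence spawning, so the same seed yields
    byte-identical outputs.
    """
    spectra = []
    for i, level in enumerate(design.levels):
        conc = {design.analyte_id: level, **design.fixed_levels}
        child_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        spectra.append(
            mixture_spectrum(models, MixtureSpec(conc, noise_sd=noise_sd, seed=child_seed), grid)
        )
    return spectra


def default_models() -> list[CompoundSpectralModel]:
    """Synthetic spectral models of the three compounds (see module docstring).

    Peak absorptivities keep the zero-order mixture absorbance at working
    levels in a realistic 0–1.5 AU window.  The shoulder of the dominant
    absorber and the widths of the two minor compounds are tuned (to the
    printed precision) so that the system presents genuine interference-free
    zero-crossing windows for every analyte — the property the real drugs'
    overlapped spectra happened to provide and on which the zero-crossing
    technique depends.
    """
    return [
        CompoundSpectralModel(
            "acetaminophen",
            bands=(
                GaussianBand(243.0, 16.0, 0.0650),  # dominant π→π* band
                GaussianBand(214.06168, 14.73983, 0.02525),  # short-wavelength shoulder
            ),
        ),
        CompoundSpectralModel(
            "diphenhydramine",
            bands=(GaussianBand(220.0, 3.88094478, 0.0500),),  # strong aromatic band
        ),
        CompoundSpectralModel(
            "pseudoephedrine",
            bands=(
                GaussianBand(208.0, 4.16099343, 0.0500),  # steep end absorption
                GaussianBand(251.0, 2.5, 0.0015),  # weak benzenoid triplet
                GaussianBand(257.0, 2.5, 0.0020),
                GaussianBand(263.0, 2.5, 0.0013),
            ),
        ),
    ]


def default_designs() -> dict[str, CalibrationDesign]:
    """The classical calibration designs: analyte series, interferents fixed.

    Acetaminophen 5–40 µg/mL with 1.5 µg/mL of each interferent;
    diphenhydramine 0.25–4 µg/mL and pseudoephedrine 0.5–5 µg/mL, each with
    acetaminophen fixed at its 25 µg/mL working level.
    """
    return {
        "acetaminophen": CalibrationDesign(
            "acetaminophen",
            levels=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0),
            fixed_levels={"diphenhydramine": 1.5, "pseudoephedrine": 1.5},
        ),
        "diphenhydramine": CalibrationDesign(
            "diphenhydramine",
            levels=(0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
            fixed_levels={"acetaminophen": 25.0, "pseudoephedrine": 1.5},
        ),
        "pseudoephedrine": CalibrationDesign(
            "pseudoephedrine",
            levels=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0),
            fixed_levels={"acetaminophen": 25.0, "diphenhydramine": 1.5},
        ),
    }
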