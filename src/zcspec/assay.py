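"""End-to-end tablet assay: calibrate, select wavelengths, quantify, back-calculate.

The tablet work-up follows the classical scheme: powder equivalent to a
fraction of one tablet into a primary volumetric flask, an aliquot of the
filtrate diluted to a final flask, the final solution measured.  A 500 mg
acetaminophen / 25 mg diphenhydramine / 30 mg pseudoephedrine tablet taken
through (¼ tablet → 100 mL, 3 mL → 100 mL) lands at 37.5 / 1.875 / 2.25
µg/mL — inside each compound's calibration range, with acetaminophen near
the top of its span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibration import (
    CalibrationCurve,
    CalibrationSummary,
    fit_calibration,
    predict_concentration,
)
from .crossings import WorkingWavelength, select_working_wavelength
from .simulate import (
    CalibrationDesign,
    CompoundSpectralModel,
    MixtureSpec,
    compound_spectrum,
    default_designs,
    default_grid,
    default_models,
    generate_calibration_dataset,
    mixture_spectrum,
)
from .spectra import DerivativeConfig, Spectrum, derivative
from .validation import ComparisonResult

__all__ = [
    "DilutionScheme",
    "CompoundAssay",
    "AssayResult",
    "DEFAULT_SCHEME",
    "DEFAULT_METHOD_CONFIGS",
    "run_assay",
    "develop_method",
    "DevelopedMethod",
    "refit_calibration",
    "simulated_tablet_assay",
    "tablet_recovery_study",
]


@dataclass(frozen=True)
class DilutionScheme:
    """Tablet → final-solution dilution arithmetic.

    ``sample_mass_fraction`` is the number of tablets represented by the
    weighed powder (e.g. 0.25 for a quarter tablet).
    """

    sample_mass_fraction: float = 0.25  # tablets
    primary_volume_ml: float = 100.0
    aliquot_ml: float = 3.0
    final_volume_ml: float = 100.0

    def __post_init__(self) -> None:
        if min(self.primary_volume_ml, self.aliquot_ml, self.final_volume_ml) <= 0:
            raise ValueError("volumes must be positive")
        if self.aliquot_ml > self.primary_volume_ml:
            raise ValueError("aliquot cannot exceed the primary volume")
        if self.sample_mass_fraction <= 0:
            raise ValueError("sample mass fraction must be positive")

    def concentration_to_content(self, conc_ug_per_ml: float) -> float:
        """Final-solution concentration (µg/mL) → content per tablet (mg)."""
        ug = (
            conc_ug_per_ml
            * self.final_volume_ml
            / self.aliquot_ml
            * self.primary_volume_ml
            / self.sample_mass_fraction
        )
        return ug / 1000.0

    def content_to_concentration(self, mg_per_tablet: float) -> float:
        """Content per tablet (mg) → expected final-solution concentration (µg/mL)."""
        ug = mg_per_tablet * 1000.0 * self.sample_mass_fraction
        return ug / self.primary_volume_ml * self.aliquot_ml / self.final_volume_ml


DEFAULT_SCHEME = DilutionScheme()

# Derivative settings used for the synthetic system: the published method's
# orders (¹D, ²D, ⁴D) with differencing widths sized for the synthetic bands
# so every order keeps a usable domain inside the 200–300 nm record.
DEFAULT_METHOD_CONFIGS: dict[str, DerivativeConfig] = {
    "acetaminophen": DerivativeConfig(order=1, delta_lambda=8.0),
    "diphenhydramine": DerivativeConfig(order=2, delta_lambda=12.0),
    "pseudoephedrine": DerivativeConfig(order=4, delta_lambda=6.0),
}


@dataclass(frozen=True)
class CompoundAssay:
    """Per-compound assay outcome."""

    compound_id: str
    measured_conc: float  # µg/mL in the final solution (mean over replicates)
    measured_sd: float
    content_per_tablet: float  # mg
    label_claim: float | None = None
    percent_of_label: float | None = None
    in_range: bool = True
    comparison: ComparisonResult | None = None


@dataclass(frozen=True)
class AssayResult:
    """Full assay outcome keyed by compound."""

    compounds: Mapping[str, CompoundAssay]
    scheme: DilutionScheme

    def __getitem__(self, compound_id: str) -> CompoundAssay:
        return self.compounds[compound_id]


def _response_at(spectrum: Spectrum, config: DerivativeConfig, wavelength: float) -> float:
    d = derivative(spectrum, config)
    return float(d.value_at(wavelength))


def run_assay(
    calibration_data: Mapping[str, CalibrationCurve | CalibrationSummary],
    unknown_spectra: Sequence[Spectrum],
    working_wavelengths: Mapping[str, WorkingWavelength],
    scheme: DilutionScheme = DEFAULT_SCHEME,
    label_claims: Mapping[str, float] | None = None,
    reference_contents: Mapping[str, Sequence[float]] | None = None,
) -> AssayResult:
    """Quantify every compound in the unknown spectra and back-calculate mg/tablet.

    Each unknown spectrum is differentiated under the compound's (order, Δλ)
    config, the amplitude at the working wavelength is converted to a
    concentration by inverse regression, and the dilution scheme maps the
    mean concentration to content per tablet.  Out-of-range concentrations
    are flagged but still reported.  If ``reference_contents`` holds a second
    method's per-replicate contents, a paired-t/F comparison is attached.
    """
    from .validation import compare_methods

    results: dict[str, CompoundAssay] = {}
    for cid, ww in working_wavelengths.items():
        curve = calibration_data[cid]
        cfg = ww.config or DerivativeConfig(order=ww.order, delta_lambda=ww.delta_lambda)
        concs = []
        flags = []
        for spec in unknown_spectra:
            est = predict_concentration(curve, _response_at(spec, cfg, ww.wavelength))
            concs.append(est.value)
            flags.append(est.in_range)
        conc_arr = np.asarray(concs)
        mean_conc = float(conc_arr.mean())
        content = scheme.concentration_to_content(mean_conc)
        label = label_claims.get(cid) if label_claims else None
        comparison = None
        if reference_contents and cid in reference_contents:
            per_rep = [scheme.concentration_to_content(c) for c in concs]
            comparison = compare_methods(per_rep, list(reference_contents[cid]))
        results[cid] = CompoundAssay(
            compound_id=cid,
            measured_conc=mean_conc,
            measured_sd=float(conc_arr.std(ddof=1)) if conc_arr.size > 1 else 0.0,
            content_per_tablet=content,
            label_claim=label,
            percent_of_label=100.0 * content / label if label else None,
            in_range=all(flags),
            comparison=comparison,
        )
    return AssayResult(compounds=results, scheme=scheme)


@dataclass(frozen=True)
class DevelopedMethod:
    """Working wavelength + calibration curve per compound, ready for assay."""

    working_wavelengths: dict[str, WorkingWavelength]
    curves: dict[str, CalibrationCurve]
    configs: dict[str, DerivativeConfig]


def develop_method(
    models: Sequence[CompoundSpectralModel] | None = None,
    designs: Mapping[str, CalibrationDesign] | None = None,
    configs: Mapping[str, DerivativeConfig] | None = None,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    relative_tol: float = 0.005,
) -> DevelopedMethod:
    """Develop the zero-crossing method on simulated (or default) spectra.

    For each analyte: simulate its calibration series, differentiate pure
    interferent spectra at their fixed design levels, select the working
    wavelength (interferent |D| within ``relative_tol`` of its own maximum,
    score = analyte signal × calibration linearity), and fit the calibration
    line at the selected wavelength.
    """
    models = list(models) if models is not None else default_models()
    designs = dict(designs) if designs is not None else default_designs()
    configs = dict(configs) if configs is not None else DEFAULT_METHOD_CONFIGS
    wl_grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    by_id = {m.compound_id: m for m in models}

    working: dict[str, WorkingWavelength] = {}
    curves: dict[str, CalibrationCurve] = {}
    for cid, design in designs.items():
        cfg = configs[cid]
        cal_spectra = generate_calibration_dataset(
            models, design, noise_sd=noise_sd, seed=seed, grid=wl_grid
        )
        cal_d = [derivative(s, cfg) for s in cal_spectra]
        analyte_ref = max(design.levels)
        analyte_d = derivative(compound_spectrum(by_id[cid], analyte_ref, wl_grid), cfg)
        interferent_d = [
            derivative(compound_spectrum(by_id[iid], level, wl_grid), cfg)
            for iid, level in design.fixed_levels.items()
        ]
        ww = select_working_wavelength(
            analyte_d,
            interferent_d,
            cal_d,
            concentrations=design.levels,
            relative_tol=relative_tol,
            analyte_id=cid,
        )
        responses = [float(d.value_at(ww.wavelength)) for d in cal_d]
        curves[cid] = fit_calibration(
            design.levels, responses, analyte_id=cid, wavelength=ww.wavelength, order=cfg.order
        )
        working[cid] = ww
    return DevelopedMethod(working_wavelengths=working, curves=curves, configs=dict(configs))


def refit_calibration(
    method: DevelopedMethod,
    models: Sequence[CompoundSpectralModel] | None = None,
    designs: Mapping[str, CalibrationDesign] | None = None,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DevelopedMethod:
    """Re-measure the calibration curves at the method's fixed wavelengths.

    Working wavelengths stay as developed (method development is done once,
    on pure standards); only the calibration responses are re-simulated,
    e.g. for a fresh analytical run with instrument noise.
    """
    models = list(models) if models is not None else default_models()
    designs = dict(designs) if designs is not None else default_designs()
    wl_grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    curves: dict[str, CalibrationCurve] = {}
    for cid, design in designs.items():
        cfg = method.configs[cid]
        ww = method.working_wavelengths[cid]
        cal = generate_calibration_dataset(models, design, noise_sd=noise_sd, seed=seed, grid=wl_grid)
        responses = [float(derivative(s, cfg).value_at(ww.wavelength)) for s in cal]
        curves[cid] = fit_calibration(
            design.levels, responses, analyte_id=cid, wavelength=ww.wavelength, order=cfg.order
        )
    return DevelopedMethod(
        working_wavelengths=dict(method.working_wavelengths), curves=curves, configs=dict(method.configs)
    )


def tablet_recovery_study(
    n_replicates: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    scans_per_replicate: int = 3,
    true_contents_mg: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Mean recovery error (%) per compound over repeated simulated assays.

    The method is developed once on noiseless standards (fixed working
    wavelengths); each replicate then re-measures the calibration curves and
    the tablet solution with fresh noise and quantifies all three compounds
    (``scans_per_replicate`` spectra per tablet solution, the classical
    triplicate).  Returns 100·(mean found − true)/true keyed by compound.
    """
    if true_contents_mg is None:
        from .simulate import TABLET_LABEL_MG

        true_contents_mg = TABLET_LABEL_MG
    base = develop_method()
    errors: dict[str, list[float]] = {cid: [] for cid in true_contents_mg}
    for rep in range(n_replicates):
        method = (
            refit_calibration(base, noise_sd=noise_sd, seed=seed * 100003 + rep)
            if noise_sd > 0
            else base
        )
        res = simulated_tablet_assay(
            method,
            true_contents_mg,
            noise_sd=noise_sd,
            seed=seed * 200003 + rep,
            n_replicates=scans_per_replicate,
        )
        for cid, ca in res.compounds.items():
            errors[cid].append(ca.percent_of_label - 100.0)
    return {cid: float(np.mean(v)) for cid, v in errors.items()}


def simulated_tablet_assay(
    method: DevelopedMethod,
    true_contents_mg: Mapping[str, float],
    scheme: DilutionScheme = DEFAULT_SCHEME,
    models: Sequence[CompoundSpectralModel] | None = None,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> AssayResult:
    """Simulate tablet-solution spectra at the label-implied concentrations
    and run the full assay against a developed method."""
    models = list(models) if models is not None else default_models()
    wl_grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    true_conc = {
        cid: scheme.content_to_concentration(mg) for cid, mg in true_contents_mg.items()
    }
    unknowns = []
    for i in range(n_replicates):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        unknowns.append(
            mixture_spectrum(models, MixtureSpec(true_conc, noise_sd=noise_sd, seed=child), wl_grid)
        )
    return run_assay(
        method.curves,
        unknowns,
        method.working_wavelengths,
        scheme=scheme,
        label_claims=dict(true_contents_mg),
    )
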