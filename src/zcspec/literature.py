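"""Published reference values for the three-drug zero-crossing assay.

Validation statistics reported for the simultaneous determination of
acetaminophen, diphenhydramine hydrochloride and pseudoephedrine
hydrochloride in tablets by derivative spectrophotometry (¹D 281.5 nm,
²D 226.0 nm, ⁴D 218.0 nm on a 200–300 nm record).  These are literature
fixture values: the experimental spectra behind them were never tabulated,
so the coefficients, recoveries and tablet contents serve as reference
inputs and qualitative checks, not as quantities this package can recompute
from raw data.
"""

from __future__ import annotations

from types import MappingProxyType

__all__ = [
    "CALIBRATION_TABLE",
    "PRECISION_TABLE",
    "RECOVERY",
    "TABLET_COMPARISON",
    "T_CRITICAL_DF4",
    "F_CRITICAL_DF22",
    "ALPHA",
]

ALPHA = 0.05
T_CRITICAL_DF4 = 2.776  # two-sided t, df = 4
F_CRITICAL_DF22 = 19.00  # upper F, df = (2, 2)

# Reported six-curve calibration statistics (response = derivative amplitude,
# X in µg/mL).  linear_range_alternate records the wider range quoted in the
# method summary; the tabulated/prepared 5–40 µg/mL range is the default.
CALIBRATION_TABLE = MappingProxyType(
    {
        "acetaminophen": MappingProxyType(
            dict(
                order=1,
                delta_lambda=28.0,
                wavelength=281.5,
                linear_range=(5.0, 40.0),
                linear_range_alternate=(5.0, 50.0),
                slope=0.00295,
                intercept=-0.0024,
                sd_slope=5.5e-5,
                rsd_slope_percent=1.86,
                ci_slope=4.4e-5,
                sd_intercept=0.00047,
                ci_intercept=0.00037,
                r=0.999,
                loq=1.59,
                lod=0.53,
                n_curves=6,
            )
        ),
        "diphenhydramine": MappingProxyType(
            dict(
                order=2,
                delta_lambda=31.5,
                wavelength=226.0,
                linear_range=(0.25, 4.0),
                slope=0.01193,
                intercept=0.01275,
                sd_slope=0.00036,
                rsd_slope_percent=2.98,
                ci_slope=0.00029,
                sd_intercept=0.00070,
                ci_intercept=0.00056,
                r=0.997,
                loq=0.86,
                lod=0.28,
                n_curves=6,
            )
        ),
        "pseudoephedrine": MappingProxyType(
            dict(
                order=4,
                delta_lambda=27.0,
                wavelength=218.0,
                linear_range=(0.5, 5.0),
                slope=0.03598,
                intercept=0.0603,
                sd_slope=0.00081,
                rsd_slope_percent=2.25,
                ci_slope=0.00065,
                sd_intercept=0.0031,
                ci_intercept=0.0025,
                r=0.996,
                loq=0.59,
                lod=0.19,
                n_curves=6,
            )
        ),
    }
)

# Accuracy/precision rows: level → (found_mean, found_sd, cv%, error%),
# within-day n = 3, between-day n = 9.
PRECISION_TABLE = MappingProxyType(
    {
        "acetaminophen": MappingProxyType(
            {
                5.00: dict(within=(5.08, 0.08, 1.57, 1.60), between=(5.03, 0.11, 2.19, 0.60)),
                20.00: dict(within=(19.78, 0.05, 0.25, -1.10), between=(19.84, 0.32, 1.61, -0.80)),
                40.00: dict(within=(39.92, 0.20, 0.50, -0.20), between=(40.07, 0.44, 1.10, 0.18)),
            }
        ),
        "diphenhydramine": MappingProxyType(
            {
                0.50: dict(within=(0.50, 0.01, 2.00, 0.00), between=(0.50, 0.01, 2.00, 0.00)),
                2.00: dict(within=(1.99, 0.04, 2.01, -0.50), between=(2.01, 0.03, 1.49, 0.50)),
                4.00: dict(within=(3.94, 0.03, 0.76, -1.50), between=(3.97, 0.05, 1.26, -0.75)),
            }
        ),
        "pseudoephedrine": MappingProxyType(
            {
                1.00: dict(within=(0.97, 0.02, 2.06, -3.00), between=(0.98, 0.02, 2.04, -2.00)),
                3.00: dict(within=(3.02, 0.05, 1.66, 0.07), between=(3.01, 0.05, 1.66, 0.33)),
                5.00: dict(within=(4.95, 0.08, 1.62, -0.10), between=(4.97, 0.06, 1.21, -0.60)),
            }
        ),
    }
)

# Standard-addition recoveries, percent (mean ± SD).
RECOVERY = MappingProxyType(
    {
        "acetaminophen": (101.5, 1.4),
        "diphenhydramine": (99.3, 1.3),
        "pseudoephedrine": (100.1, 0.9),
    }
)

# Tablet assay vs the reference HPLC method: label claim (mg), found mg
# (mean, sd) for each method, and the reported t and F statistics.
TABLET_COMPARISON = MappingProxyType(
    {
        "acetaminophen": dict(
            label_mg=500.00, proposed=(507.25, 7.20), hplc=(507.49, 4.48), t=0.960, f=0.553
        ),
        "diphenhydramine": dict(
            label_mg=25.00, proposed=(25.00, 0.81), hplc=(25.08, 0.40), t=0.915, f=0.391
        ),
        "pseudoephedrine": dict(
            label_mg=30.00, proposed=(29.92, 0.26), hplc=(30.03, 0.57), t=0.838, f=0.354
        ),
    }
)
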