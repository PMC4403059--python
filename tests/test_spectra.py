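"""Spectrum container, resampling and derivative operators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from zcspec import (
    ConfigError,
    DerivativeConfig,
    RangeError,
    Spectrum,
    SpectrumError,
    derivative,
    derivative_noise_sd,
    read_jcamp,
    read_spectrum_csv,
    resample,
    uniform_grid,
    write_spectrum_csv,
)


def gaussian_spectrum(center=250.0, sigma=8.0, start=200.0, stop=300.0, step=0.5, amp=1.0):
    wl = uniform_grid(start, stop, step)
    return Spectrum(wl, amp * np.exp(-((wl - center) ** 2) / (2 * sigma**2)))


class TestSpectrumInvariants:
    def test_rejects_non_uniform_grid(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([200.0, 201.0, 203.0]), np.zeros(3))

    def test_rejects_decreasing_grid(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([203.0, 202.0, 201.0]), np.zeros(3))

    def test_rejects_nan_absorbance(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([200.0, 201.0, 202.0]), np.array([0.0, np.nan, 0.0]))

    def test_rejects_short_spectrum(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([200.0, 201.0]), np.zeros(2))


class TestResample:
    def test_identity_on_same_grid(self):
        s = gaussian_spectrum()
        r = resample(s, 200.0, 300.0, 0.5)
        np.testing.assert_allclose(r.absorbance, s.absorbance, atol=1e-12)

    def test_linear_interpolation_midpoint(self):
        # ramp from 0 AU at 200 nm to 1 AU at 300 nm
        wl = np.array([200.0, 250.0, 300.0])
        s = Spectrum(wl, np.array([0.0, 0.5, 1.0]))
        r = resample(s, 225.0, 275.0, 25.0)
        np.testing.assert_allclose(r.absorbance, [0.25, 0.5, 0.75], atol=1e-12)

    def test_round_trip_against_piecewise_linear_oracle(self):
        rng = np.random.default_rng(42)
        wl = uniform_grid(200.0, 300.0, 1.0)
        s = Spectrum(wl, rng.normal(0.5, 0.2, wl.size))
        fine = resample(s, 200.0, 300.0, 0.25)
        back = resample(fine, 200.0, 300.0, 1.0)

        def oracle(x):  # brute-force piecewise-linear evaluation
            for i in range(wl.size - 1):
                if wl[i] <= x <= wl[i + 1]:
                    t = (x - wl[i]) / (wl[i + 1] - wl[i])
                    return (1 - t) * s.absorbance[i] + t * s.absorbance[i + 1]
            raise AssertionError

        for x, v in zip(fine.wavelengths[::37], fine.absorbance[::37]):
            assert abs(v - oracle(float(x))) < 1e-12
        np.testing.assert_allclose(back.absorbance, s.absorbance, atol=1e-12)

    def test_meta_preserved(self):
        s = Spectrum(np.arange(200.0, 203.0), np.zeros(3), meta={"sample": "t1"})
        assert resample(s, 200.0, 202.0, 1.0).meta["sample"] == "t1"

    def test_out_of_range_raises(self):
        with pytest.raises(RangeError):
            resample(gaussian_spectrum(), 150.0, 250.0, 0.5)


class TestDerivativeExamples:
    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    @pytest.mark.parametrize("method,poly", [("finite_difference", None), ("savitzky_golay", 5)])
    def test_constant_spectrum_has_zero_derivative(self, order, method, poly):
        wl = uniform_grid(200.0, 300.0, 0.5)
        s = Spectrum(wl, np.full(wl.size, 0.7))
        d = derivative(s, DerivativeConfig(order, 10.0, method=method, sg_polyorder=poly))
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("delta", [2.0, 6.0, 17.3])
    @pytest.mark.parametrize("method,poly", [("finite_difference", None), ("savitzky_golay", 3)])
    def test_linear_ramp_first_derivative(self, delta, method, poly):
        wl = uniform_grid(200.0, 300.0, 0.5)
        s = Spectrum(wl, 0.01 * wl)
        d = derivative(s, DerivativeConfig(1, delta, method=method, sg_polyorder=poly))
        np.testing.assert_allclose(d.values, 0.01, atol=1e-10)

    def test_gaussian_band_matches_analytic_first_derivative(self):
        # closed-form oracle: dA/dλ = −(λ−250)/σ² · A(λ)
        s = gaussian_spectrum(center=250.0, sigma=8.0)
        d = derivative(s, DerivativeConfig(1, 2.0))
        analytic = -(d.wavelengths - 250.0) / 64.0 * np.exp(
            -((d.wavelengths - 250.0) ** 2) / (2 * 64.0)
        )
        peak = np.abs(analytic).max()
        assert np.abs(d.values - analytic).max() < 0.01 * peak

    def test_domain_shrinks_by_half_window_per_order(self):
        s = gaussian_spectrum(step=0.5)
        d = derivative(s, DerivativeConfig(2, 10.0))
        # Δλ=10 on 0.5 nm grid: half-window 10 points = 5 nm per application
        assert d.wavelengths[0] == pytest.approx(210.0)
        assert d.wavelengths[-1] == pytest.approx(290.0)

    def test_delta_lambda_rounded_to_even_grid_steps(self):
        s = gaussian_spectrum(step=0.1)
        d = derivative(s, DerivativeConfig(2, 31.5))
        assert d.effective_delta_lambda == pytest.approx(31.6)

    def test_window_wider_than_spectrum_raises(self):
        s = gaussian_spectrum(step=0.5)
        with pytest.raises(ConfigError):
            derivative(s, DerivativeConfig(4, 60.0))

    def test_delta_below_two_grid_steps_raises(self):
        s = gaussian_spectrum(step=0.5)
        with pytest.raises(ConfigError):
            derivative(s, DerivativeConfig(1, 0.2))

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            DerivativeConfig(0, 2.0)
        with pytest.raises(ConfigError):
            DerivativeConfig(5, 2.0)
        with pytest.raises(ConfigError):
            DerivativeConfig(1, -1.0)
        with pytest.raises(ConfigError):
            DerivativeConfig(2, 4.0, method="savitzky_golay", sg_polyorder=2)
        with pytest.raises(ConfigError):
            DerivativeConfig(2, 4.0, method="smoothing_spline")


class TestDerivativeProperties:
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        order=st.integers(1, 4),
        method_poly=st.sampled_from([("finite_difference", None), ("savitzky_golay", 5)]),
    )
    def test_linearity(self, a, b, order, method_poly):
        """derivative(a·S1 + b·S2) = a·dS1 + b·dS2 — the additivity the
        zero-crossing technique relies on."""
        method, poly = method_poly
        wl = uniform_grid(200.0, 300.0, 1.0)
        rng = np.random.default_rng(7)
        s1 = Spectrum(wl, rng.normal(0.5, 0.2, wl.size))
        s2 = Spectrum(wl, np.exp(-((wl - 240.0) ** 2) / 200.0))
        cfg = DerivativeConfig(order, 10.0, method=method, sg_polyorder=poly)
        mix = Spectrum(wl, a * s1.absorbance + b * s2.absorbance)
        lhs = derivative(mix, cfg).values
        rhs = a * derivative(s1, cfg).values + b * derivative(s2, cfg).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_order_composition_finite_difference(self):
        """Applying the order-1 operator twice equals order-2 with the same Δλ."""
        s = gaussian_spectrum(step=0.5)
        cfg1 = DerivativeConfig(1, 8.0)
        d1 = derivative(s, cfg1)
        d11 = derivative(Spectrum(d1.wavelengths, d1.values), cfg1)
        d2 = derivative(s, DerivativeConfig(2, 8.0))
        np.testing.assert_allclose(d11.wavelengths, d2.wavelengths, atol=1e-9)
        np.testing.assert_allclose(d11.values, d2.values, rtol=1e-10, atol=1e-14)

    def test_grid_refinement_leaves_values_unchanged(self):
        """Doubling grid density changes a smooth band's derivative only by
        discretization error."""
        coarse = gaussian_spectrum(step=0.4)
        fine = gaussian_spectrum(step=0.2)
        cfg = DerivativeConfig(2, 8.0)
        dc = derivative(coarse, cfg)
        df = derivative(fine, cfg)
        common = np.interp(dc.wavelengths, df.wavelengths, df.values)
        assert np.abs(dc.values - common).max() < 5e-4 * np.abs(dc.values).max() + 1e-12

    def test_noise_sd_propagation_matches_monte_carlo(self):
        """Predicted derivative noise SD agrees with simulation."""
        wl = uniform_grid(200.0, 300.0, 0.5)
        cfg = DerivativeConfig(2, 10.0)
        rng = np.random.default_rng(11)
        vals = np.stack(
            [derivative(Spectrum(wl, rng.normal(0, 0.002, wl.size)), cfg).values for _ in range(400)]
        )
        predicted = derivative_noise_sd(cfg, 0.5, 0.002)
        assert vals.std() == pytest.approx(predicted, rel=0.1)


class TestFileFormats:
    def test_csv_round_trip_with_comments(self, tmp_path):
        s = gaussian_spectrum()
        f = tmp_path / "spec.csv"
        write_spectrum_csv(s, f)
        text = "# instrument: simulated\n" + f.read_text()
        f.write_text(text)
        r = read_spectrum_csv(f)
        np.testing.assert_allclose(r.absorbance, s.absorbance, atol=1e-9)

    def test_csv_missing_columns_raises(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("lambda,signal\n200,0.1\n201,0.2\n202,0.3\n")
        with pytest.raises(SpectrumError):
            read_spectrum_csv(f)

    def test_jcamp_xydata_import(self, tmp_path):
        f = tmp_path / "spec.jdx"
        f.write_text(
            "##TITLE=synthetic test spectrum\n"
            "##JCAMP-DX=4.24\n"
            "##XUNITS=NANOMETERS\n##YUNITS=ABSORBANCE\n"
            "##XFACTOR=1.0\n##YFACTOR=0.001\n"
            "##XYDATA=(X++(Y..Y))\n"
            "200.0 100 110 120 130\n"
            "204.0 140 150 160 170\n"
            "208.0 180 190 200 210\n"
            "##END=\n"
        )
        s = read_jcamp(f)
        assert len(s) == 12
        assert s.wavelengths[0] == pytest.approx(200.0)
        assert s.wavelengths[-1] == pytest.approx(211.0)
        np.testing.assert_allclose(s.absorbance[:4], [0.1, 0.11, 0.12, 0.13], atol=1e-12)
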