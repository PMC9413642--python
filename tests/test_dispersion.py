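"""Dispersion module: kappa, KK transform, empirical fits, anisotropy."""

import math

import numpy as np
import pytest

from tissueoptics.dispersion import (
    AnisotropyFit,
    ScatteringSpectrumFit,
    anisotropy_from_scattering,
    fit_anisotropy_spectrum,
    fit_dispersion_model,
    fit_reduced_scattering_spectrum,
    kappa_from_absorption,
    kk_refractive_index,
    mus_from_collimated,
)
from tissueoptics.synthetic_data import PRESET_TABLE

BRAIN_N_POINTS = [(532, 1.3761), (660, 1.3676), (785, 1.3626), (980, 1.3541)]
BRAIN_G_POINTS = [(532, 0.80), (660, 0.83), (785, 0.85), (980, 0.90)]


class TestKappa:
    @pytest.mark.parametrize(
        "wl,mu_a,kap",
        [(532, 4.0, 1.69e-5), (660, 1.2, 6.30e-6), (980, 0.0, 0.0)],
    )
    def test_values(self, wl, mu_a, kap):
        assert kappa_from_absorption(wl, mu_a) == pytest.approx(kap, rel=5e-3, abs=1e-12)


class TestDispersionFits:
    def test_cauchy_noiseless_recovery(self):
        # B in nm^2, C in nm^4; all three terms contribute above 1e-3
        A, B, C = 1.35, 5e3, 2e8
        lam = np.array([450.0, 600.0, 800.0, 1000.0])
        n = A + B / lam**2 + C / lam**4
        curve = fit_dispersion_model(list(zip(lam, n)), "cauchy")
        assert curve.A == pytest.approx(A, rel=1e-8)
        assert curve.B == pytest.approx(B, rel=1e-6)
        assert curve.C == pytest.approx(C, rel=1e-6)
        assert np.max(np.abs(curve(lam) - n)) < 1e-10

    @pytest.mark.parametrize("model", ["cauchy", "conrady", "cornu"])
    def test_self_family_residual_vanishes(self, model):
        params = {"cauchy": (1.33, 4e3, 1e8), "conrady": (1.33, 12.0, 2e6),
                  "cornu": (1.33, 20.0, 150.0)}[model]
        lam = np.linspace(480.0, 1000.0, 8)
        A, B, C = params
        if model == "cauchy":
            n = A + B / lam**2 + C / lam**4
        elif model == "conrady":
            n = A + B / lam + C / lam**3.5
        else:
            n = A + B / (lam - C)
        curve = fit_dispersion_model(list(zip(lam, n)), model)
        assert np.max(np.abs(curve(lam) - n)) < 1e-10

    def test_brain_points_fit_monotone_decreasing(self):
        for model in ("cauchy", "conrady", "cornu"):
            curve = fit_dispersion_model(BRAIN_N_POINTS, model)
            grid = np.linspace(532.0, 980.0, 64)
            assert np.all(np.diff(curve(grid)) < 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_dispersion_model([(500, 1.35), (600, 1.34)], "cauchy")

    def test_duplicate_wavelengths_rejected(self):
        pts = [(500, 1.35), (500, 1.351), (600, 1.34)]
        with pytest.raises(ValueError, match="duplicate"):
            fit_dispersion_model(pts, "cauchy")


class TestKramersKronig:
    @staticmethod
    def lorentz_curves(lam, lam0=700.0, strength=2e-4, gamma_rel=0.05):
        """Weak Lorentz oscillator: analytic (n, kappa) pair (KK-consistent)."""
        w, w0 = 1.0 / lam, 1.0 / lam0
        chi = strength * w0**2 / (w0**2 - w**2 - 1j * gamma_rel * w0 * w)
        return 1.0 + chi.real / 2.0, chi.imag / 2.0

    def test_zero_kappa_returns_anchor(self):
        lam = np.linspace(400.0, 1000.0, 101)
        n = kk_refractive_index(lam, np.zeros_like(lam), (700.0, 1.36))
        assert np.allclose(n, 1.36, atol=1e-12)

    def test_lorentz_oscillator_oracle(self):
        lam = np.linspace(100.0, 5000.0, 6000)
        n_true, kap = self.lorentz_curves(lam)
        anchor = (3000.0, float(np.interp(3000.0, lam, n_true)))
        n_kk = kk_refractive_index(lam, kap, anchor)
        away = np.abs(lam - 700.0) > 0.3 * 700.0
        err = np.max(np.abs(n_kk - n_true)[away])
        assert err < 0.02 * np.ptp(n_true)

    def test_linearity(self):
        lam = np.linspace(300.0, 2000.0, 800)
        _, kap = self.lorentz_curves(lam)
        base = kk_refractive_index(lam, kap, (1500.0, 1.4)) - 1.4
        double = kk_refractive_index(lam, 2.0 * kap, (1500.0, 1.4)) - 1.4
        assert np.allclose(double, 2.0 * base, atol=1e-12)

    def test_anchor_outside_grid_rejected(self):
        lam = np.linspace(400.0, 900.0, 50)
        with pytest.raises(ValueError, match="anchor"):
            kk_refractive_index(lam, np.zeros_like(lam), (1200.0, 1.35))


class TestScatteringFromCollimated:
    def test_beer_lambert_inverse(self):
        T_c = math.exp(-(4.0 + 71.5) * 0.05)
        assert mus_from_collimated(T_c, 0.05, 4.0) == pytest.approx(71.5, rel=1e-12)

    def test_unit_transmittance(self):
        assert mus_from_collimated(1.0, 0.05, 0.0) == 0.0

    def test_negative_result_flagged_not_hidden(self):
        with pytest.warns(UserWarning, match="mu_s"):
            out = mus_from_collimated(math.exp(-0.1), 0.05, 10.0)
        assert out < 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mus_from_collimated(0.0, 0.05, 1.0)
        with pytest.raises(ValueError):
            mus_from_collimated(1.2, 0.05, 1.0)


class TestAnisotropy:
    @pytest.mark.parametrize(
        "mu_sp,mu_s,g",
        [(14.3, 71.5, 0.80), (10.0, 10.0, 0.0), (5.9, 59.0, 0.90)],
    )
    def test_values(self, mu_sp, mu_s, g):
        assert anisotropy_from_scattering(mu_sp, mu_s) == pytest.approx(g, abs=1e-12)

    def test_reduced_exceeding_full_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            anisotropy_from_scattering(12.0, 10.0)

    def test_consistency_with_km_mapping(self, all_presets):
        """g = 1 - mu_s'/mu_s returns the stored anisotropy for every preset."""
        for pre in all_presets:
            p = pre.properties
            assert anisotropy_from_scattering(p.mu_s_reduced, p.mu_s) == pytest.approx(
                p.g, abs=1e-9
            )


class TestSpectrumFits:
    def test_rayleigh_mie_noiseless_recovery(self):
        truth = ScatteringSpectrumFit(20.0, 0.2, 1.0)
        pts = [(w, truth(w)) for w in (532.0, 660.0, 785.0, 980.0)]
        fit = fit_reduced_scattering_spectrum(pts)
        assert fit.a == pytest.approx(20.0, rel=1e-6)
        assert fit.f_Ray == pytest.approx(0.2, abs=1e-6)
        assert fit.b_Mie == pytest.approx(1.0, rel=1e-6)

    def test_row_order_invariance(self):
        truth = ScatteringSpectrumFit(18.0, 0.35, 1.4)
        pts = [(w, truth(w)) for w in (532.0, 660.0, 785.0, 980.0)]
        a = fit_reduced_scattering_spectrum(pts)
        b = fit_reduced_scattering_spectrum(pts[::-1])
        assert (a.a, a.f_Ray, a.b_Mie) == (b.a, b.f_Ray, b.b_Mie)

    def test_pure_rayleigh_limit(self):
        lam = np.array([500.0, 600.0, 750.0, 900.0])
        mus = 15.0 * (lam / 500.0) ** -4.0
        fit = fit_reduced_scattering_spectrum(list(zip(lam, mus)))
        assert fit(600.0) == pytest.approx(15.0 * (600.0 / 500.0) ** -4, rel=1e-6)

    def test_preset_spectra_fit_decreasing(self):
        for tissue in ("skin", "skull", "brain"):
            pts = [(wl, PRESET_TABLE[(tissue, wl)][1]) for wl in (532, 660, 785, 980)]
            fit = fit_reduced_scattering_spectrum(pts)
            grid = np.linspace(532.0, 980.0, 64)
            assert np.all(np.diff(fit(grid)) < 0)


class TestAnisotropyFits:
    def test_saturating_recovery_up_to_identifiability(self):
        # a + b(1-exp(-(l-c)/d)) is identified only through
        # (a+b, b e^{c/d}, d): assert those combinations.
        truth = AnisotropyFit("saturating", 0.8, 0.1, 600.0, 200.0)
        pts = [(w, truth(w)) for w in (500.0, 650.0, 800.0, 950.0, 1100.0)]
        fit = fit_anisotropy_spectrum(pts, "saturating")
        assert fit.residual_norm < 1e-8
        assert fit.a + fit.b == pytest.approx(0.9, abs=1e-6)
        assert fit.d == pytest.approx(200.0, rel=1e-4)
        assert fit.b * math.exp(fit.c / fit.d) == pytest.approx(
            0.1 * math.exp(3.0), rel=1e-4
        )

    def test_brain_g_fit_increasing(self):
        fit = fit_anisotropy_spectrum(BRAIN_G_POINTS, "saturating")
        grid = np.linspace(532.0, 980.0, 64)
        assert np.all(np.diff(fit(grid)) > 0)

    def test_biexponential_reproduces_data(self):
        fit = fit_anisotropy_spectrum(BRAIN_G_POINTS, "biexponential")
        lam = np.array([p[0] for p in BRAIN_G_POINTS])
        g = np.array([p[1] for p in BRAIN_G_POINTS])
        assert np.max(np.abs(fit(lam) - g)) < 5e-3

    def test_constant_g_flagged_degenerate(self):
        pts = [(w, 0.85) for w in (532.0, 660.0, 785.0, 980.0)]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_anisotropy_spectrum(pts, "saturating")
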