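"""Wavelength-dependent optical-property modelling.

Covers the spectral side of tissue characterisation:

* the imaginary refractive index kappa(lambda) = lambda * mu_a / (4 pi);
* reconstruction of the real index n(lambda) from kappa(lambda) by a
  subtractive Kramers-Kronig (KK) transform anchored at one measured point;
* classical empirical dispersion fits (Cauchy, Conrady, Cornu);
* the Rayleigh + Mie decomposition of the reduced-scattering spectrum

      mu_s'(l) = a [ f_Ray (l/500nm)^-4 + (1 - f_Ray) (l/500nm)^-b_Mie ];

* the scattering coefficient from collimated (ballistic) transmittance,
  mu_s = -ln(T_c)/d - mu_a (Beer-Lambert);
* the anisotropy factor g = 1 - mu_s'/mu_s and empirical g(lambda) fits
  (saturating rising exponential and biexponential forms).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

_log = logging.getLogger(__name__)

__all__ = [
    "DispersionCurve",
    "ScatteringSpectrumFit",
    "AnisotropyFit",
    "kappa_from_absorption",
    "fit_dispersion_model",
    "kk_refractive_index",
    "mus_from_collimated",
    "anisotropy_from_scattering",
    "fit_reduced_scattering_spectrum",
    "fit_anisotropy_spectrum",
]

_NM_TO_CM = 1e-7


@dataclass(frozen=True)
class DispersionCurve:
    """Fitted empirical dispersion n(lambda) of one of three families.

    cauchy:  n = A + B/l^2 + C/l^4      (B in nm^2, C in nm^4)
    conrady: n = A + B/l + C/l^3.5      (B in nm, C in nm^3.5)
    cornu:   n = A + B/(l - C)          (B in nm, C in nm)
    """

    model: str
    A: float
    B: float
    C: float
    support: tuple[float, float]
    residual_norm: float = 0.0

    def __call__(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, dtype=float)
        if self.model == "cauchy":
            out = self.A + self.B / lam**2 + self.C / lam**4
        elif self.model == "conrady":
            out = self.A + self.B / lam + self.C / lam**3.5
        elif self.model == "cornu":
            out = self.A + self.B / (lam - self.C)
        else:  # pragma: no cover - constructor validates
            raise ValueError(f"unknown model {self.model!r}")
        return out if out.ndim else float(out)

    def __post_init__(self) -> None:
        if self.model not in ("cauchy", "conrady", "cornu"):
            raise ValueError(f"model must be cauchy|conrady|cornu, got {self.model!r}")
        lo, hi = self.support
        if self.model == "cornu" and lo <= self.C <= hi:
            raise ValueError(f"cornu pole C={self.C} lies inside support {self.support}")


@dataclass(frozen=True)
class ScatteringSpectrumFit:
    """Rayleigh + Mie decomposition of a reduced-scattering spectrum.

    a: mu_s' at 500 nm (cm^-1); f_Ray: Rayleigh fraction in [0, 1];
    b_Mie: Mie scatterer-size exponent (>= 0).
    """

    a: float
    f_Ray: float
    b_Mie: float
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not 0.0 <= self.f_Ray <= 1.0:
            raise ValueError(f"f_Ray must be in [0, 1], got {self.f_Ray}")
        if self.b_Mie < 0:
            raise ValueError(f"b_Mie must be >= 0, got {self.b_Mie}")

    def __call__(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, dtype=float) / 500.0
        out = self.a * (self.f_Ray * lam**-4.0 + (1.0 - self.f_Ray) * lam**-self.b_Mie)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class AnisotropyFit:
    """Empirical g(lambda) fit.

    saturating:    g = a + b (1 - exp(-(l - c)/d))
    biexponential: g = a exp(b l) + c exp(d l)
    """

    form: str
    a: float
    b: float
    c: float
    d: float
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("saturating", "biexponential"):
            raise ValueError(f"form must be saturating|biexponential, got {self.form!r}")

    def __call__(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, dtype=float)
        if self.form == "saturating":
            out = self.a + self.b * (1.0 - np.exp(-(lam - self.c) / self.d))
        else:
            out = self.a * np.exp(self.b * lam) + self.c * np.exp(self.d * lam)
        return out if out.ndim else float(out)


def kappa_from_absorption(wavelength_nm: float, mu_a: float) -> float:
    """Imaginary index kappa = lambda * mu_a / (4 pi), lambda converted to cm."""
    if wavelength_nm < 0 or mu_a < 0:
        raise ValueError("wavelength and mu_a must be >= 0")
    return wavelength_nm * _NM_TO_CM * mu_a / (4.0 * math.pi)


def fit_dispersion_model(points, model: str) -> DispersionCurve:
    """Least-squares fit of one empirical dispersion family to (lambda, n) data.

    Cauchy and Conrady are linear in (A, B, C) and solved by lstsq; Cornu is
    nonlinear in its pole C and solved by bounded least squares with the pole
    constrained below the shortest data wavelength.
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (wavelength, n) points")
    lam, n = pts[:, 0], pts[:, 1]
    if np.unique(lam).size != lam.size:
        raise ValueError("duplicate wavelengths make the design rank-deficient")
    support = (float(lam.min()), float(lam.max()))

    if model == "cauchy":
        design = np.column_stack([np.ones_like(lam), lam**-2.0, lam**-4.0])
    elif model == "conrady":
        design = np.column_stack([np.ones_like(lam), lam**-1.0, lam**-3.5])
    elif model == "cornu":
        design = None
    else:
        raise ValueError(f"model must be cauchy|conrady|cornu, got {model!r}")

    if design is not None:
        coef, *_ = np.linalg.lstsq(design, n, rcond=None)
        resid = float(np.linalg.norm(design @ coef - n))
        return DispersionCurve(model, *map(float, coef), support=support, residual_norm=resid)

    def residual(p):
        A, B, C = p
        return A + B / (lam - C) - n

    c_hi = support[0] - 1e-3
    fit = least_squares(
        residual,
        x0=[float(n.mean()), 1.0, 0.0],
        bounds=([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, c_hi]),
    )
    return DispersionCurve(
        "cornu", *map(float, fit.x), support=support,
        residual_norm=float(np.linalg.norm(fit.fun)),
    )


def kk_refractive_index(wavelengths_nm, kappa, anchor: tuple[float, float]):
    """Real index n(lambda) from kappa(lambda) by a subtractive KK transform.

    The frequency-domain Kramers-Kronig relation, rewritten in wavelength,
    reads

        n(l) = 1 + (2/pi) PV Int_0^inf  kappa(L) / [ L (1 - L^2/l^2) ] dL.

    The integral is truncated to the supplied grid and evaluated at every
    grid point; the principal value at L = l is handled by splitting off the
    simple pole, integrating the regularised part by the trapezoid rule and
    the pole analytically over the grid extent.  The unknown truncation
    constant is absorbed by anchoring: the returned curve satisfies
    n(anchor lambda) = anchor n exactly (additive shift).

    Parameters
    ----------
    wavelengths_nm : array
        Strictly increasing sample grid covering the output range, nm.
    kappa : array
        kappa sampled on the same grid.
    anchor : (lambda_nm, n)
        One trusted refractive-index point; lambda must lie inside the grid.

    Returns
    -------
    ndarray of n evaluated on ``wavelengths_nm``.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    kap = np.asarray(kappa, dtype=float)
    if lam.ndim != 1 or lam.size < 5:
        raise ValueError("need a 1-D grid with >= 5 samples")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if kap.shape != lam.shape:
        raise ValueError("kappa must be sampled on the wavelength grid")
    lam_a, n_a = anchor
    if not lam[0] <= lam_a <= lam[-1]:
        raise ValueError(f"anchor wavelength {lam_a} outside grid [{lam[0]}, {lam[-1]}]")

    def pv_integral(l0: float) -> float:
        # integrand = kappa(L) l0^2 / (L (l0-L)(l0+L)) = h(L)/(l0-L),
        # h(L) = kappa(L) l0^2 / (L (l0+L)); subtract the pole at L=l0.
        h = kap * l0 * l0 / (lam * (l0 + lam))
        h0 = float(np.interp(l0, lam, kap)) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            reg = (h - h0) / (l0 - lam)
        # at the singular sample the regularised integrand tends to -h'(l0)
        sing = np.nonzero(np.abs(lam - l0) < 1e-12 * max(l0, 1.0))[0]
        if sing.size:
            i = int(sing[0])
            j0, j1 = max(i - 1, 0), min(i + 1, lam.size - 1)
            reg[i] = -(h[j1] - h[j0]) / (lam[j1] - lam[j0])
        integral = float(np.trapezoid(reg, lam))
        if lam[0] < l0 < lam[-1]:
            integral += h0 * math.log((l0 - lam[0]) / (lam[-1] - l0))
        return (2.0 / math.pi) * integral

    vals = np.array([pv_integral(l0) for l0 in lam])
    shift = n_a - float(np.interp(lam_a, lam, vals))
    return vals + shift


def mus_from_collimated(T_c: float, d: float, mu_a: float) -> float:
    """Scattering coefficient from ballistic transmittance.

    Beer-Lambert: T_c = exp(-(mu_a + mu_s) d), so mu_s = -ln(T_c)/d - mu_a.
    A negative result (mu_a exceeding the total attenuation) is returned
    as-is with a warning rather than silently clipped.
    """
    if not 0.0 < T_c <= 1.0:
        raise ValueError(f"T_c must be in (0, 1], got {T_c}")
    if d <= 0:
        raise ValueError(f"d must be > 0, got {d}")
    mu_s = -math.log(T_c) / d - mu_a
    if mu_s < 0:
        warnings.warn(
            f"mu_s = {mu_s:.4g} < 0: mu_a={mu_a} exceeds the total attenuation "
            f"-ln(T_c)/d = {-math.log(T_c) / d:.4g}",
            stacklevel=2,
        )
    return mu_s


def anisotropy_from_scattering(mu_s_reduced: float, mu_s: float) -> float:
    """Anisotropy factor g = 1 - mu_s'/mu_s."""
    if mu_s_reduced <= 0 or mu_s <= 0:
        raise ValueError("mu_s_reduced and mu_s must be > 0")
    if mu_s_reduced > mu_s * (1.0 + 1e-12):
        raise ValueError(f"mu_s_reduced={mu_s_reduced} > mu_s={mu_s} is unphysical")
    return max(1.0 - mu_s_reduced / mu_s, 0.0)


def fit_reduced_scattering_spectrum(points) -> ScatteringSpectrumFit:
    """Bounded nonlinear least-squares fit of the Rayleigh+Mie spectrum.

    Initialisation is deterministic (a = max mu_s', f_Ray = 0.5, b_Mie = 1)
    so the fit is invariant to input row order and reruns.
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (wavelength, mu_s') points")
    lam, mus = pts[:, 0], pts[:, 1]
    x = lam / 500.0

    def residual(p):
        a, f, b = p
        return a * (f * x**-4.0 + (1.0 - f) * x**-b) - mus

    fit = least_squares(
        residual,
        x0=[float(mus.max()), 0.5, 1.0],
        bounds=([1e-12, 0.0, 0.0], [np.inf, 1.0, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    resid = float(np.linalg.norm(fit.fun))
    if not fit.success:
        raise RuntimeError(
            f"scattering-spectrum fit did not converge: {fit.message}; "
            f"residual norm {resid:.3g}"
        )
    return ScatteringSpectrumFit(*map(float, fit.x), residual_norm=resid)


def fit_anisotropy_spectrum(points, form: str = "saturating") -> AnisotropyFit:
    """Least-squares fit of an empirical g(lambda) form.

    Constant (zero-variance) g data leave the shape parameters unidentified;
    that degenerate case is reported as an error rather than returning an
    arbitrary parameter vector.
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (wavelength, g) points for 4-parameter forms")
    lam, g = pts[:, 0], pts[:, 1]
    if np.any((g < 0) | (g >= 1)):
        raise ValueError("g values must be in [0, 1)")
    if np.ptp(g) < 1e-12:
        raise ValueError("constant g data: shape parameters are unidentifiable")

    lam_mid = float(lam.mean())
    lam_span = float(lam.max() - lam.min())
    if form == "saturating":
        def residual(p):
            a, b, c, d = p
            return a + b * (1.0 - np.exp(-(lam - c) / d)) - g
        x0 = [float(g.min()), float(np.ptp(g)), float(lam.min()), lam_span]
        bounds = ([-1.0, -2.0, 0.0, 1e-3], [2.0, 2.0, 2.0 * lam.max(), 1e5])
    elif form == "biexponential":
        def residual(p):
            a, b, c, d = p
            return a * np.exp(b * lam) + c * np.exp(d * lam) - g
        x0 = [float(g.mean()), 1.0 / (10.0 * lam_mid), -float(np.ptp(g)), -1.0 / lam_mid]
        bounds = ([-10.0, -0.1, -10.0, -0.1], [10.0, 0.1, 10.0, 0.1])
    else:
        raise ValueError(f"form must be saturating|biexponential, got {form!r}")

    fit = least_squares(residual, x0=x0, bounds=bounds, xtol=1e-15, ftol=1e-15)
    resid = float(np.linalg.norm(fit.fun))
    if not fit.success:
        raise RuntimeError(
            f"anisotropy fit ({form}) did not converge: {fit.message}; "
            f"residual norm {resid:.3g}"
        )
    return AnisotropyFit(form, *map(float, fit.x), residual_norm=resid)
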