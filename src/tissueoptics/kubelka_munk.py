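"""Two-flux (Kubelka-Munk) slab model: forward, inverse, and derived optics.

The Kubelka-Munk (KM) model describes diffuse light in a turbid slab with two
counter-propagating fluxes, one along the incident beam and one backscattered.
Its two phenomenological coefficients -- the KM scattering coefficient ``S_km``
and the KM absorption coefficient ``A_km`` (both cm^-1) -- admit a closed-form
solution for the diffuse reflectance ``R_d`` and diffuse transmittance ``T_d``
of a slab of thickness ``d``, and a closed-form inversion from measured
``(R_d, T_d, d)`` back to ``(S_km, A_km)``.

We use the classic Kottler solution

    R_d = sinh(u) / (x sinh(u) + y cosh(u)),
    T_d = y      / (x sinh(u) + y cosh(u)),   u = S_km * y * d,

with the auxiliary variables x = 1 + A_km/S_km and y = sqrt(x^2 - 1).  This
form and the inversion

    x = (1 + R_d^2 - T_d^2) / (2 R_d),  y = sqrt(x^2 - 1),
    S_km = ln[(1 - R_d (x - y)) / T_d] / (y d),  A_km = (x - 1) S_km

are an exactly consistent forward/inverse pair.  (A common variant swaps
cosh/sinh in the forward denominator; that variant is *not* inverted by the
expressions above, so the consistent pair is implemented here.)

KM coefficients connect to transport optical properties through

    A_km = 2 mu_a,      S_km = (3/4) mu_s' - (1/4) mu_a,

with mu_s' = mu_s (1 - g) the reduced scattering coefficient.

All lengths are cm, all coefficients cm^-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

_log = logging.getLogger(__name__)

__all__ = [
    "OpticalProperties",
    "KMCoefficients",
    "SlabMeasurement",
    "optical_to_km",
    "km_forward",
    "km_inverse",
    "km_to_optical",
    "penetration_depth",
    "fresnel_normal_reflectance",
    "KMInversionError",
]


class KMInversionError(ValueError):
    """Raised when a measurement pair cannot be inverted (unphysical x < 1,
    vanishing transmittance, or violated energy bounds)."""


@dataclass(frozen=True)
class OpticalProperties:
    """Transport optical properties of one tissue at one wavelength.

    Attributes
    ----------
    wavelength : float
        Vacuum wavelength, nm.
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s_reduced : float
        Reduced scattering coefficient mu_s' = mu_s (1 - g), cm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering angle).
    n : float
        Real refractive index.
    mu_s : float or None
        Scattering coefficient, cm^-1 (optional; consistent with g if given).
    kappa : float or None
        Imaginary part of the complex refractive index (optional).
    """

    wavelength: float
    mu_a: float
    mu_s_reduced: float
    g: float = 0.0
    n: float = 1.0
    mu_s: float | None = None
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_reduced < 0:
            raise ValueError(f"mu_s_reduced must be >= 0, got {self.mu_s_reduced}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must be in [0, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.mu_s is not None:
            expected = self.mu_s * (1.0 - self.g)
            scale = max(abs(expected), abs(self.mu_s_reduced), 1e-300)
            if abs(expected - self.mu_s_reduced) > 1e-9 * scale:
                raise ValueError(
                    f"inconsistent mu_s={self.mu_s}, g={self.g}: "
                    f"mu_s*(1-g)={expected} != mu_s_reduced={self.mu_s_reduced}"
                )


@dataclass(frozen=True)
class KMCoefficients:
    """Kubelka-Munk coefficient pair with the auxiliary variables x, y.

    x = 1 + A_km/S_km and y = sqrt(x^2 - 1) are derived in __post_init__
    when not supplied.
    """

    S_km: float
    A_km: float
    x: float = field(default=float("nan"))
    y: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.S_km <= 0:
            raise ValueError(f"S_km must be > 0, got {self.S_km}")
        if self.A_km < 0:
            raise ValueError(f"A_km must be >= 0, got {self.A_km}")
        if math.isnan(self.x):
            object.__setattr__(self, "x", 1.0 + self.A_km / self.S_km)
        if math.isnan(self.y):
            object.__setattr__(self, "y", math.sqrt(max(self.x * self.x - 1.0, 0.0)))
        if self.x < 1.0 - 1e-12:
            raise ValueError(f"x must be >= 1, got {self.x}")
        if abs(self.y * self.y - (self.x * self.x - 1.0)) > 1e-9 * max(1.0, self.x * self.x):
            raise ValueError("y^2 != x^2 - 1")


@dataclass(frozen=True)
class SlabMeasurement:
    """One integrating-sphere record: diffuse quantities for a slab.

    R_d and T_d are fractions of incident power; T_t (total) and T_c
    (collimated, ballistic) are optional and satisfy T_d = T_t - T_c.
    Thickness d is in cm.
    """

    wavelength: float
    R_d: float
    T_d: float
    d: float
    T_t: float | None = None
    T_c: float | None = None

    def __post_init__(self) -> None:
        for name in ("R_d", "T_d"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        # energy: R_d + T_d <= 1, equality only in the conservative A_km = 0 limit
        if self.R_d + self.T_d > 1.0:
            raise ValueError(
                f"R_d + T_d must be <= 1 (energy), got {self.R_d} + {self.T_d}"
            )
        if self.d <= 0:
            raise ValueError(f"thickness d must be > 0, got {self.d}")
        if self.T_t is not None and self.T_c is not None:
            if abs(self.T_d - (self.T_t - self.T_c)) > 1e-9:
                raise ValueError(
                    f"T_d={self.T_d} inconsistent with T_t-T_c={self.T_t - self.T_c}"
                )


def optical_to_km(props: OpticalProperties) -> KMCoefficients:
    """Convert transport properties to KM coefficients.

    A_km = 2 mu_a, S_km = (3/4) mu_s' - (1/4) mu_a.  Requires
    mu_s' > mu_a / 3 so that S_km is positive (the KM picture needs a
    scattering-dominated slab).
    """
    A_km = 2.0 * props.mu_a
    S_km = 0.75 * props.mu_s_reduced - 0.25 * props.mu_a
    if S_km <= 0:
        raise ValueError(
            f"S_km = 3/4*mu_s' - 1/4*mu_a = {S_km} <= 0 for "
            f"mu_s'={props.mu_s_reduced}, mu_a={props.mu_a}; "
            "the KM mapping requires mu_s' > mu_a/3"
        )
    return KMCoefficients(S_km=S_km, A_km=A_km)


def km_forward(coeffs: KMCoefficients, d: float) -> tuple[float, float]:
    """Diffuse reflectance and transmittance of a slab of thickness d (cm).

    Evaluated in an overflow-safe form obtained by multiplying numerator and
    denominator by 2 exp(-u):

        R_d = -expm1(-2u) / [(x+y) - (x-y) exp(-2u)]
        T_d = 2 y exp(-u) / [(x+y) - (x-y) exp(-2u)]

    The conservative case A_km = 0 (x = 1, y = 0) is the analytic limit
    R_d = S d / (1 + S d), T_d = 1 / (1 + S d).
    """
    if d <= 0:
        raise ValueError(f"thickness d must be > 0, got {d}")
    S, x, y = coeffs.S_km, coeffs.x, coeffs.y
    if coeffs.A_km == 0.0 or y == 0.0:
        sd = S * d
        return sd / (1.0 + sd), 1.0 / (1.0 + sd)
    u = S * y * d
    e2 = math.exp(-2.0 * u)
    denom = (x + y) - (x - y) * e2
    R_d = -math.expm1(-2.0 * u) / denom
    T_d = 2.0 * y * math.exp(-u) / denom
    return R_d, T_d


def km_inverse(meas: SlabMeasurement) -> KMCoefficients:
    """Recover KM coefficients from a measured (R_d, T_d, d) triple.

    Exact inverse of :func:`km_forward` on noiseless data.  Raises
    :class:`KMInversionError` for unphysical pairs (x < 1) and for
    vanishing transmittance, where the log diverges and a thinner sample
    is needed.
    """
    R_d, T_d, d = meas.R_d, meas.T_d, meas.d
    if R_d <= 0:
        raise KMInversionError("R_d must be > 0 for KM inversion")
    if T_d <= 0:
        raise KMInversionError(
            "T_d must be > 0 for KM inversion; for opaque samples remeasure "
            "in a thinner-sample regime"
        )
    x = (1.0 + R_d * R_d - T_d * T_d) / (2.0 * R_d)
    if x < 1.0 - 1e-12:
        raise KMInversionError(
            f"unphysical measurement pair (R_d={R_d}, T_d={T_d}): x={x} < 1"
        )
    x = max(x, 1.0)
    y = math.sqrt(x * x - 1.0)
    if y < 1e-9:
        # conservative limit: R_d = S d/(1+S d), T_d = 1/(1+S d)
        S = R_d / (T_d * d)
        return KMCoefficients(S_km=S, A_km=0.0, x=1.0, y=0.0)
    S = math.log((1.0 - R_d * (x - y)) / T_d) / (y * d)
    if S <= 0:
        raise KMInversionError(
            f"inverted S_km={S} <= 0 from (R_d={R_d}, T_d={T_d}, d={d})"
        )
    return KMCoefficients(S_km=S, A_km=(x - 1.0) * S)


def km_to_optical(
    coeffs: KMCoefficients, g: float, wavelength: float = float("nan"), n: float = 1.0
) -> OpticalProperties:
    """Convert KM coefficients back to transport properties.

    mu_a = A_km / 2, mu_s' = (4 S_km + mu_a) / 3, mu_s = mu_s' / (1 - g).
    """
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must be in [0, 1), got {g}")
    mu_a = coeffs.A_km / 2.0
    mu_s_reduced = (4.0 * coeffs.S_km + mu_a) / 3.0
    mu_s = mu_s_reduced / (1.0 - g)
    return OpticalProperties(
        wavelength=wavelength,
        mu_a=mu_a,
        mu_s_reduced=mu_s_reduced,
        g=g,
        n=n,
        mu_s=mu_s,
    )


def penetration_depth(mu_a: float, mu_s_reduced: float) -> float:
    """Optical penetration depth delta = 1/sqrt(3 mu_a (mu_a + mu_s')), cm.

    The 1/e fluence decay depth of the diffusion approximation
    (delta = 1/mu_eff).  Diverges for a non-absorbing medium, which is
    reported as a domain error.
    """
    if mu_a <= 0:
        raise ValueError(
            f"penetration depth is infinite for mu_a={mu_a}; requires mu_a > 0"
        )
    if mu_s_reduced < 0:
        raise ValueError(f"mu_s_reduced must be >= 0, got {mu_s_reduced}")
    return 1.0 / math.sqrt(3.0 * mu_a * (mu_a + mu_s_reduced))


def fresnel_normal_reflectance(n: float, kappa: float = 0.0) -> float:
    """Specular reflectance at normal incidence from vacuum onto a medium
    with complex index n + i*kappa:  R_F = ((n-1)^2 + k^2)/((n+1)^2 + k^2)."""
    if n < 1.0:
        raise ValueError(f"n must be >= 1, got {n}")
    if kappa < 0.0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    return ((n - 1.0) ** 2 + kappa**2) / ((n + 1.0) ** 2 + kappa**2)
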