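"""Synthetic measurement generator for the rabbit-head tissue presets.

No public dataset accompanies the ex-vivo measurements this package
analyses, so every pipeline stage is exercised against synthetic data with
the same statistical structure: integrating-sphere slab measurements
(diffuse reflectance R_d, diffuse/total/collimated transmittance) of 0.5 mm
tissue slabs, and Abbe-refractometer critical-angle readings.

The tissue presets are the measured optical properties of rabbit head skin,
skull and brain at the four laser wavelengths 532, 660, 785 and 980 nm
(mu_a, mu_s', g, n per tissue/wavelength).  The sphere generator produces
R_d/T_d either from the closed-form Kubelka-Munk slab solution
(``engine="km"``, exactly invertible by the analysis) or from the
Monte-Carlo transport model (``engine="mc"``, carrying the KM model error),
plus the ballistic Beer-Lambert T_c; multiplicative Gaussian noise emulates
measurement error.  Refractometer readings encode each preset's index in a
critical angle sin(theta_c) = n_sample / n_prism with additive RI-equivalent
noise (instrument accuracy 2e-4).

Glass slide interfaces are not modelled by default; an optional normal-
incidence Fresnel specular loss can be toggled for the sphere generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from tissueoptics.kubelka_munk import (
    OpticalProperties,
    SlabMeasurement,
    fresnel_normal_reflectance,
    km_forward,
    optical_to_km,
)

_log = logging.getLogger(__name__)

__all__ = [
    "TissuePreset",
    "MeasurementSet",
    "RefractometerReading",
    "PRESET_TABLE",
    "PRESET_WAVELENGTHS",
    "make_preset",
    "generate_sphere_measurements",
    "generate_refractometer_series",
]

# Measured rabbit head tissue properties:
# (tissue, wavelength nm) -> (mu_a cm^-1, mu_s' cm^-1, g, n)
PRESET_TABLE: dict[tuple[str, int], tuple[float, float, float, float]] = {
    ("skin", 532): (4.4, 15.0, 0.80, 1.3769),
    ("skin", 660): (2.8, 14.1, 0.82, 1.3691),
    ("skin", 785): (1.5, 11.4, 0.85, 1.3631),
    ("skin", 980): (0.8, 6.0, 0.90, 1.3551),
    ("skull", 532): (4.7, 16.0, 0.80, 1.3784),
    ("skull", 660): (3.0, 14.8, 0.81, 1.3695),
    ("skull", 785): (1.7, 11.5, 0.90, 1.3637),
    ("skull", 980): (0.9, 7.2, 0.90, 1.3596),
    ("brain", 532): (4.0, 14.3, 0.80, 1.3761),
    ("brain", 660): (1.2, 10.5, 0.83, 1.3676),
    ("brain", 785): (1.0, 8.7, 0.85, 1.3626),
    ("brain", 980): (0.8, 5.9, 0.90, 1.3541),
}

PRESET_WAVELENGTHS = tuple(sorted({w for _, w in PRESET_TABLE}))
PRESET_TISSUES = ("skin", "skull", "brain")

# anatomical layer thicknesses, cm (skin 1.1 mm, skull 1 mm, brain 3 mm)
ANATOMICAL_THICKNESS = {"skin": 0.11, "skull": 0.10, "brain": 0.30}
# thickness of the slabs prepared for spectral measurements, cm (0.5 mm)
SPECTRAL_SLAB_THICKNESS = 0.05


@dataclass(frozen=True)
class TissuePreset:
    """One tissue/wavelength preset with its slab geometries."""

    tissue: str
    wavelength: float
    properties: OpticalProperties
    slab_thickness_spectral: float = SPECTRAL_SLAB_THICKNESS
    anatomical_thickness: float = 0.0


@dataclass(frozen=True)
class MeasurementSet:
    """A reproducible batch of synthetic sphere measurements."""

    records: tuple[SlabMeasurement, ...]
    noise_sd: float
    seed: int
    engine: str


@dataclass(frozen=True)
class RefractometerReading:
    """One Abbe-refractometer critical-angle reading."""

    wavelength: float
    critical_angle_deg: float
    prism_n: float
    noise_sd: float

    def recovered_n(self) -> float:
        """Invert the critical angle: n = n_prism * sin(theta_c)."""
        return self.prism_n * math.sin(math.radians(self.critical_angle_deg))


def make_preset(tissue: str, wavelength: float) -> TissuePreset:
    """Look up the preset for one tissue/wavelength pair.

    mu_s is derived from the stored reduced coefficient as mu_s'/(1-g).
    """
    key = (tissue, int(wavelength))
    if key not in PRESET_TABLE:
        raise ValueError(
            f"no preset for {tissue!r} at {wavelength} nm; supported tissues "
            f"{PRESET_TISSUES} at wavelengths {PRESET_WAVELENGTHS}"
        )
    mu_a, mu_sp, g, n = PRESET_TABLE[key]
    props = OpticalProperties(
        wavelength=float(wavelength), mu_a=mu_a, mu_s_reduced=mu_sp, g=g, n=n,
        mu_s=mu_sp / (1.0 - g),
    )
    return TissuePreset(
        tissue=tissue,
        wavelength=float(wavelength),
        properties=props,
        anatomical_thickness=ANATOMICAL_THICKNESS[tissue],
    )


def generate_sphere_measurements(
    preset: TissuePreset,
    noise_sd: float = 0.01,
    seed: int = 0,
    engine: str = "km",
    n_photons: int = 100_000,
    include_specular_loss: bool = False,
    thickness: float | None = None,
) -> MeasurementSet:
    """Synthesize an integrating-sphere record for one preset.

    R_d and T_d come from the chosen forward engine at the spectral slab
    thickness; the ballistic transmittance is T_c = exp(-(mu_a + mu_s) d)
    and T_t = T_d + T_c.  Multiplicative Gaussian noise of standard
    deviation ``noise_sd`` (fraction) is applied independently per quantity;
    draws leaving [0, 1) are clipped with a log message.

    engine="km" uses the closed-form two-flux slab solution (exactly
    invertible by the analysis); engine="mc" runs the Monte-Carlo transport
    model with matched boundaries, which carries the KM model error.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    d = thickness if thickness is not None else preset.slab_thickness_spectral
    p = preset.properties
    if engine == "km":
        R_d, T_d = km_forward(optical_to_km(p), d)
    elif engine == "mc":
        from tissueoptics.mc_transport import Layer, LayerStack, run_mc

        stack = LayerStack(
            [Layer(mu_a=p.mu_a, mu_s=p.mu_s, g=p.g, n=p.n, thickness=d)],
            boundary_mode="matched",
        )
        res = run_mc(stack, n_photons=n_photons, seed=seed, grid=(0.01, 0.005, 50, 12))
        T_c_clean = math.exp(-(p.mu_a + p.mu_s) * d)
        R_d, T_d = res.R_d, max(res.T_t - T_c_clean, 0.0)
    else:
        raise ValueError(f"engine must be km|mc, got {engine!r}")

    T_c = math.exp(-(p.mu_a + p.mu_s) * d)
    if include_specular_loss:
        rf = fresnel_normal_reflectance(p.n, p.kappa or 0.0)
        scale = 1.0 - rf
        R_d, T_d, T_c = R_d * scale, T_d * scale, T_c * scale

    rng = np.random.default_rng(seed)
    vals = np.array([R_d, T_d, T_c])
    if noise_sd > 0:
        vals = vals * (1.0 + noise_sd * rng.standard_normal(3))
        clipped = np.clip(vals, 0.0, 1.0 - 1e-12)
        if np.any(clipped != vals):
            _log.warning("noisy measurement clipped into [0, 1) for %s at %s nm",
                         preset.tissue, preset.wavelength)
        vals = clipped
    R_d, T_d, T_c = map(float, vals)
    rec = SlabMeasurement(
        wavelength=preset.wavelength, R_d=R_d, T_d=T_d, d=d,
        T_t=T_d + T_c, T_c=T_c,
    )
    return MeasurementSet(records=(rec,), noise_sd=noise_sd, seed=seed, engine=engine)


def generate_refractometer_series(
    tissue: str,
    noise_sd: float = 0.0002,
    seed: int = 0,
    prism_n: float = 1.7,
) -> list[RefractometerReading]:
    """Critical-angle readings for one tissue at all preset wavelengths.

    Noise is additive in refractive-index units (instrument accuracy
    2e-4 RI) and mapped through the arcsine to the angle, so the inversion
    n = prism_n sin(theta_c) recovers n + noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    readings = []
    for wl in PRESET_WAVELENGTHS:
        n = make_preset(tissue, wl).properties.n
        if prism_n <= n:
            raise ValueError(
                f"prism index {prism_n} must exceed the sample index {n} "
                "for total internal reflection at the prism interface"
            )
        n_noisy = n + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)
        theta_c = math.degrees(math.asin(n_noisy / prism_n))
        readings.append(RefractometerReading(
            wavelength=float(wl), critical_angle_deg=theta_c,
            prism_n=prism_n, noise_sd=noise_sd,
        ))
    return readings
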