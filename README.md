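# tissueoptics

Optical-property estimation and light-transport modelling for layered head
tissue (skin, skull, brain), built around four laser wavelengths
(532, 660, 785, 980 nm).

Knowing a tissue's absorption coefficient μa, scattering coefficient μs,
anisotropy g, refractive index n and the derived reduced scattering
μs′ = μs(1−g) is what lets optogenetics, photother­apy and diagnostic work
predict where laser light actually goes inside the head. This package
implements the full desk side of that workflow for researchers in
biophotonics:

* **Kubelka–Munk inversion** — closed-form two-flux slab model connecting
  integrating-sphere measurements (diffuse reflectance R_d, diffuse
  transmittance T_d, thickness d) with μa and μs′:

      x = (1 + R_d² − T_d²) / (2 R_d),  y = √(x²−1),
      S_KM = ln[(1 − R_d(x−y))/T_d]/(y d),  A_KM = (x−1) S_KM,
      μa = A_KM/2,   μs′ = (4 S_KM + μa)/3,

  plus the penetration depth δ = 1/√(3 μa (μa+μs′)), μs from collimated
  transmittance (Beer–Lambert), and g = 1 − μs′/μs.
* **Dispersion modelling** — κ(λ) = λμa/4π, Kramers–Kronig reconstruction
  of n(λ), Cauchy/Conrady/Cornu fits, the Rayleigh+Mie μs′(λ)
  decomposition, and empirical g(λ) fits.
* **Monte-Carlo photon transport** — weighted multilayer simulation
  (Henyey–Greenstein scattering, Russian roulette, matched or Fresnel
  boundaries, numba-compiled) producing R_d, T_t, absorbed fraction and
  r–z fluence-rate maps for slab stacks such as skin/skull/brain.
* **FEM diffusion solver** — steady-state diffusion approximation
  −∇·(D∇Φ) + μaΦ = S on a 3×2 cm rectangle with a point source, P1
  triangular elements, Robin partial-current boundaries, and the χ²
  two-parameter inverse fit recovering (μa, D) from boundary fluence.
* **Synthetic data** — a generator emulating the integrating-sphere and
  Abbe-refractometer measurements for the twelve tissue/wavelength presets,
  with configurable multiplicative noise, so the entire pipeline is
  testable without instrument data.

## Worked example

Invert a synthetic brain measurement at 532 nm and predict fluence:

```python
from tissueoptics import (
    make_preset, generate_sphere_measurements, km_inverse, km_to_optical,
    penetration_depth, three_layer_fluence,
)

preset = make_preset("brain", 532)            # mu_a=4.0, mu_s'=14.3, g=0.80
ms = generate_sphere_measurements(preset, noise_sd=0.0)   # 0.5 mm slab
rec = ms.records[0]
print(f"Rd={rec.R_d:.4f}  Td={rec.T_d:.4f}")
props = km_to_optical(km_inverse(rec), g=preset.properties.g)
print(f"mu_a={props.mu_a:.3f} cm^-1  mu_s'={props.mu_s_reduced:.3f} cm^-1")
print(f"delta={penetration_depth(props.mu_a, props.mu_s_reduced):.4f} cm")

res = three_layer_fluence(532, n_photons=100_000, seed=42)
print(f"R_d={res.R_d:.4f}  T_t={res.T_t:.4f}  absorbed={res.absorbed:.4f}")
```

prints

```
Rd=0.2357  Td=0.4431
mu_a=4.000 cm^-1  mu_s'=14.300 cm^-1
delta=0.0675 cm
R_d=0.2219  T_t=0.0007  absorbed=0.7774
```

The 0.5 mm brain slab at 532 nm reflects 23.6 % and diffusely transmits
44.3 % of the incident light; inversion returns exactly the generating
coefficients, with a 0.68 mm penetration depth. In the three-layer head
stack at 532 nm nearly 78 % of the light is absorbed before reaching the
bottom of the brain layer, while the same run at 980 nm transmits 13 % —
the scattering and absorption drop at longer wavelengths, so the fluence
at depth grows.

## Analysis

`analysis/` holds the numbered end-to-end drivers, each writing its tables
under `results/`:

1. `01_generate_measurements.py` — synthetic sphere + refractometer data;
2. `02_invert_properties.py` — Kubelka–Munk inversion into the
   per-tissue/wavelength property table and penetration depths;
3. `03_fit_dispersion.py` — dispersion, scattering-spectrum and anisotropy
   fits, plus a Kramers–Kronig n(λ) reconstruction;
4. `04_mc_fluence.py` — Monte-Carlo fluence maps of the three-layer head
   model at each wavelength (CSV + log-fluence PNG);
5. `05_fem_fluence.py` — FEM surface-fluence profiles and the χ² inverse
   demonstration.

There is also a CLI (`tissueoptics generate|invert|fit-dispersion|
simulate-mc|solve-fem|run-all`) and a library pipeline
(`tissueoptics.pipeline.run_pipeline`) that chains the same stages from a
single serializable config with per-stage seeds.

See `docs/methods.md` for the models, numerical choices and limitations.

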