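# Methods

This note records the models implemented in `tissueoptics`, the numerical
choices behind them, and what the synthetic data can and cannot say about
real measurements.

## Two-flux (Kubelka–Munk) slab model

Diffuse light in a turbid slab is described by two counter-propagating
fluxes with phenomenological coefficients S_KM (scattering) and A_KM
(absorption), both cm⁻¹. With x = 1 + A_KM/S_KM, y = √(x²−1) and
u = S_KM·y·d, the closed-form solution for a slab of thickness d is

    R_d = sinh u / (x sinh u + y cosh u),
    T_d = y      / (x sinh u + y cosh u),

and the closed-form inversion from a measured (R_d, T_d, d) is

    x = (1 + R_d² − T_d²) / (2 R_d),   y = √(x² − 1),
    S_KM = ln[(1 − R_d (x − y)) / T_d] / (y d),   A_KM = (x − 1) S_KM.

Two denominator conventions for the forward solution circulate in the
literature, differing by a cosh/sinh swap. Only the form above is exactly
inverted by the expressions for x, S_KM and A_KM, which we verified both
algebraically and against a matrix-exponential solution of the two-flux
ODE boundary-value problem; the package therefore implements this
consistent pair. The forward model is evaluated after multiplying through
by 2e⁻ᵘ so it cannot overflow at large optical depth, and the conservative
limit A_KM = 0 uses the analytic limit R_d = S d/(1+S d) rather than the
0/0 expression.

The bridge to transport coefficients is A_KM = 2 μa,
S_KM = (3/4) μs′ − (1/4) μa, which requires μs′ > μa/3 (scattering-dominated
slabs — true for all the tissue presets). An unphysical measured pair with
x < 1 is algebraically equivalent to R_d + T_d > 1, so the energy bound is
enforced at record construction.

Units are cm and cm⁻¹ throughout the library; measurement tables carry
thickness in mm (bench convention) and are converted exactly once at the
I/O layer.

Penetration depth uses the diffusion-approximation expression
δ = 1/√(3 μa (μa + μs′)); it is reported as a domain error for μa = 0.

## Spectral models

* **Imaginary index**: κ(λ) = λ μa(λ)/(4π), with λ converted to cm.
* **Kramers–Kronig**: the real index is reconstructed from κ(λ) by the
  wavelength-domain transform
  n(λ) = const + (2/π) PV ∫ κ(Λ)/[Λ(1 − Λ²/λ²)] dΛ,
  truncated to the supplied grid. The principal value is handled by
  splitting off the simple pole (subtracting its residue value
  κ(λ)/2, integrating the regularised part by trapezoid and the pole
  analytically over the grid extent). Truncation bias is absorbed by a
  subtractive anchor: the curve is shifted to pass through one trusted
  (λ, n) point. Against a weak Lorentz-oscillator oracle the
  reconstruction is accurate to well under 2 % of the dispersion amplitude
  away from the line centre.
* **Empirical dispersion fits**: Cauchy (A + B/λ² + C/λ⁴) and Conrady
  (A + B/λ + C/λ^3.5) are linear least squares; Cornu (A + B/(λ−C)) is
  bounded nonlinear least squares with the pole constrained below the data
  range. With wavelengths in nm the λ⁻⁴ column is ~10⁻¹¹, so the Cauchy C
  coefficient is intrinsically ill-conditioned in double precision when its
  contribution to n is below ~10⁻⁶; fits always reproduce the curve to
  <10⁻¹⁰ but tiny C values are not individually meaningful.
* **Scattering spectrum**: μs′(λ) = a[f_Ray (λ/500 nm)⁻⁴ +
  (1−f_Ray)(λ/500 nm)^−b_Mie], fitted by bounded nonlinear least squares
  with a deterministic initialisation (a = max μs′, f_Ray = 0.5,
  b_Mie = 1), making the fit independent of row order and reruns.
* **Collimated channel**: Beer–Lambert gives μs = −ln(T_c)/d − μa (the
  minus sign follows from T_c < 1; a printed variant without it is a sign
  slip). A negative result, meaning μa exceeds the total attenuation, is
  returned with a warning instead of being clipped.
* **Anisotropy**: g = 1 − μs′/μs, and empirical g(λ) fits in a saturating
  rising-exponential form a + b(1 − e^−(λ−c)/d) or a biexponential
  a e^{bλ} + c e^{dλ}. The saturating form is identifiable only through
  (a+b, b e^{c/d}, d); tests assert those combinations. Constant-g data
  leave the shape parameters undetermined and are rejected as degenerate.

## Multilayer Monte-Carlo transport

The simulator follows the standard weighted multilayer scheme: pencil beam
at normal incidence; step length s = −ln ξ/(μa+μs) in the current layer;
absorption by weight decrement w μa/(μa+μs) per collision (not photon
termination); Henyey–Greenstein sampling
cos θ = [1+g² − ((1−g²)/(1−g+2gξ))²]/(2g) with the isotropic branch at
g = 0; uniform azimuth; the usual spherical direction update with the
|cos θz| ≈ 1 degenerate branch; Russian roulette below weight 10⁻⁴ with
survival probability 1/10. Boundaries are refractive-index matched by
default (the configuration the three-layer analysis assumes); a Fresnel
mode computes the unpolarized reflection probability with total internal
reflection, refracts by Snell's law, and books the specular reflection of
the entry surface into R_d so energy still closes.

Absorbed weight is tallied on a cylindrical (r, z) grid (default
dr = dz = 0.005 cm, 120×120 bins; overflow folded into the outermost
radial bin) and converted to fluence rate per unit incident power by
Φ = A/(μa ΔV N). Fluence is stored linearly; log-transformation happens
only at render time in the analysis scripts. The RNG is the Mersenne
Twister seeded inside the compiled kernel, so a run is bit-reproducible
from (stack, N, seed, grid).

Validation: Beer–Lambert transmission of a pure absorber within binomial
error; exact weight conservation for non-absorbing slabs; the plane albedo
of a semi-infinite isotropic medium with single-scattering albedo 0.9
against the published radiative-transfer value 0.41498 (within 1 %); and
the similarity relation between (μs, g) and (μs(1−g), 0) media in the
diffusive regime (within 2 %). Fresnel-mismatched boundaries trap light by
internal reflection, raising the absorbed fraction — the tests assert that
ordering rather than a naive "reflectance increases" claim, which the
simulation shows to be false for the diffuse channel.

The three-layer head model stacks skin (0.11 cm), skull (0.10 cm) and
brain (0.30 cm) with each tissue's preset properties at the chosen
wavelength. Default 10⁵ photons: statistical error on the tallies is then
≲0.5 % absolute, and a run takes a few seconds.

## Diffusion-approximation FEM

The steady-state diffusion equation −∇·(D∇Φ) + μaΦ = S with
D = 1/(3(μa+μs′)) is solved on a 3 cm × 2 cm rectangle with a unit point
source at (1.5, 1) cm, using linear (P1) triangular elements and a direct
sparse factorisation. The mesh is a structured crisscross triangulation
(four triangles per cell around a centre node), chosen so the discrete
solution is exactly mirror-symmetric about both axes of a symmetric
problem; a single-diagonal split provably breaks that symmetry at the
discretisation level. The point source is a unit load at the node nearest
the nominal position.

The physical boundary condition is the Robin partial-current relation
Φ + 2AD ∂Φ/∂ν = 0, with A an internal-reflection parameter computed from
the relative refractive index by the standard empirical polynomial
(A = 1, the matched case, by default); a homogeneous Dirichlet mode exists
for comparison. Whether the original COMSOL computation used 2-D or a 2-D
slice of 3-D, and which boundary condition, is not documented; this
implementation is genuinely 2-D, and its accuracy oracle is therefore the
2-D infinite-medium kernel Φ(r) = K0(μeff r)/(2πD), μeff = √(μa/D) — no
2-D/3-D conflation. On an h = 0.01 cm mesh the FEM solution matches the
kernel to better than 1 % for all twelve tissue presets in the window
between one transport mean free path and three penetration depths
(boundary images are negligible there because μeff·(distance to boundary)
is large).

The inverse problem minimises χ² = ½ Σ (Φ_meas − F(μa, D))² over
(log μa, log D) with Nelder–Mead (positivity by construction,
derivative-free because F is a sparse solve). On noiseless self-generated
boundary data the generating parameters are recovered to optimizer
tolerance (≪1 %); with 1 % multiplicative noise the median recovered μa
over replicates stays within 10 % of truth.

## Synthetic data generator

The generator emulates the measurement campaign the analysis assumes:

* **Sphere records**: R_d and T_d from the two-flux forward model (engine
  `km`, exactly invertible — the self-consistency configuration) or from
  the Monte-Carlo model (engine `mc`), at the 0.5 mm spectral slab
  thickness; T_c = e^−(μa+μs)d; T_t = T_d + T_c. Multiplicative Gaussian
  noise (default 1 %) per quantity, clipped to [0, 1) with a logged
  message. The km-vs-mc reflectance gap is a stable model mismatch of the
  two-flux approximation (several percent for these presets); it is
  reported by tests, not hidden.
* **Refractometer**: critical angles θc = arcsin(n/n_prism) per
  wavelength, additive noise of 2×10⁻⁴ in RI units (the instrument's
  stated accuracy). The Abbe prism index is not documented for the
  instrument; 1.7 (a typical Abbe prism) is used and recorded with every
  reading.
* **Presets**: the measured rabbit skin/skull/brain properties at
  532/660/785/980 nm, with μs derived as μs′/(1−g); anatomical layer
  thicknesses 1.1/1/3 mm; spectral slabs 0.5 mm.

Not modelled: integrating-sphere wall reflectance and port-loss
corrections, the glass slides sandwiching real samples (an optional
normal-incidence specular loss can be toggled), detector spectral
response, and the iterative adding-doubling inversion pathway (the
closed-form two-flux inversion substitutes for it, cross-checked against
the Monte-Carlo forward model). Passing tests on km-engine data therefore
demonstrate the correctness of the analysis chain, not the accuracy of
the two-flux approximation for real tissue — that gap is exactly what the
mc-engine comparison quantifies.

The thin-slab energy balance T_t ≈ 1 − (R_d + R_F) − μa·d holds only to
the linearisation gap (up to ~0.1 absolute for the strongly attenuating
presets); tests check it loosely and do not assert it exactly.

## Problem sizes and runtime choices

Unit and acceptance tests use 2.5×10⁴–2×10⁵ photons per Monte-Carlo run,
FEM meshes of h = 0.05 cm (inversions, ~5×10³ nodes) and h = 0.01 cm
(kernel-accuracy checks, ~1.2×10⁵ nodes), 10–100 noise replicates, and the
four-wavelength preset grid; these sizes keep every statistical check at
≥3σ separation while the full suite runs in a few minutes. The analysis
drivers use 10⁵ photons per wavelength (the study's own photon budget) and
h = 0.02 cm for surface profiles.

## Known limitations

* The two-flux inversion assumes diffuse illumination and a
  scattering-dominated slab; it degrades for μs′ ≲ μa/3 and for optically
  thin samples (T_d → 1).
* The Monte-Carlo model is layered-homogeneous: no lateral heterogeneity,
  no time resolution, no polarization, pencil beam by default (beam
  profiles can be emulated by convolution if needed).
* The FEM model is 2-D; absolute fluence magnitudes are per unit source
  power in the plane and are not directly comparable to 3-D measurements.
* Anisotropy g enters the analysis only through μs′/μs; the synthetic
  pathway cannot distinguish phase-function shapes beyond their first
  moment.
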