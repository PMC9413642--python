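"""Multilayer Monte-Carlo photon transport (MCML-style).

Simulates a pencil beam normally incident on a stack of plane-parallel
turbid layers, each described by absorption coefficient ``mu_a`` (cm^-1),
scattering coefficient ``mu_s`` (cm^-1), Henyey-Greenstein anisotropy ``g``,
refractive index ``n`` and thickness (cm).  Photons are propagated with the
classic weighted scheme: step lengths ``s = -ln(xi) / (mu_a + mu_s)``,
absorption by weight decrement ``w mu_a/(mu_a + mu_s)`` at each collision,
Henyey-Greenstein direction sampling, Russian roulette for low weights, and
either refractive-index-matched or Fresnel interface handling.

Tallies: diffuse reflectance ``R_d``, total transmittance ``T_t``, absorbed
fraction, and an r-z grid of absorbed weight converted to fluence rate per
unit incident power via ``phi = A / (mu_a * dV * N)`` (cm^-2).

The photon loop is compiled with numba; results are bit-reproducible for a
fixed (stack, N, seed, grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "Layer",
    "LayerStack",
    "MCResult",
    "sample_henyey_greenstein",
    "fresnel_interface",
    "run_mc",
    "three_layer_fluence",
]

_W_ROULETTE = 1e-4     # roulette threshold on photon weight
_P_SURVIVE = 0.1       # roulette survival probability


@dataclass(frozen=True)
class Layer:
    """One plane-parallel slab layer."""

    mu_a: float
    mu_s: float
    g: float
    n: float
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must be in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of layers; the first layer is illuminated from above."""

    layers: tuple[Layer, ...]
    ambient_n_top: float = 1.0
    ambient_n_bottom: float = 1.0
    boundary_mode: str = "matched"

    def __init__(self, layers, ambient_n_top=1.0, ambient_n_bottom=1.0,
                 boundary_mode="matched"):
        object.__setattr__(self, "layers", tuple(layers))
        object.__setattr__(self, "ambient_n_top", float(ambient_n_top))
        object.__setattr__(self, "ambient_n_bottom", float(ambient_n_bottom))
        object.__setattr__(self, "boundary_mode", boundary_mode)
        if not self.layers:
            raise ValueError("stack needs >= 1 layer")
        if boundary_mode not in ("matched", "fresnel"):
            raise ValueError(f"boundary_mode must be matched|fresnel, got {boundary_mode!r}")

    @property
    def interfaces(self) -> np.ndarray:
        """Depths of the layer interfaces including top (0) and bottom, cm."""
        return np.concatenate([[0.0], np.cumsum([l.thickness for l in self.layers])])

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness for l in self.layers))


@dataclass(frozen=True)
class MCResult:
    """Tallied output of one Monte-Carlo run.

    ``fluence`` is fluence rate per unit incident power on an (nr, nz)
    cylindrical grid (cm^-2); ``absorption_grid`` is the raw absorbed weight
    per bin.  In ``fresnel`` mode the specular reflection at the top surface
    is included in ``R_d``, keeping R_d + T_t + absorbed = 1.
    """

    R_d: float
    T_t: float
    absorbed: float
    fluence: np.ndarray
    absorption_grid: np.ndarray
    absorbed_by_layer: np.ndarray
    n_photons: int
    seed: int
    grid: tuple[float, float, int, int]  # dr, dz, nr, nz
    r_edges: np.ndarray = field(repr=False, default=None)
    z_edges: np.ndarray = field(repr=False, default=None)


def sample_henyey_greenstein(g: float, u: float) -> float:
    """Sample cos(theta) of the Henyey-Greenstein phase function by inverse CDF.

    ``u`` is a uniform deviate in [0, 1).  For g = 0 the distribution is
    isotropic and cos(theta) = 2u - 1.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"g must be in (-1, 1), got {g}")
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u must be in [0, 1), got {u}")
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


def fresnel_interface(n1: float, n2: float, cos_incident: float) -> tuple[float, float]:
    """Unpolarized Fresnel reflection probability and transmitted cosine.

    Returns (reflect_prob, cos_transmitted).  Total internal reflection
    gives (1.0, 0.0); matched indices give (0.0, cos_incident).
    """
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 < cos_incident <= 1.0:
        raise ValueError(f"cos_incident must be in (0, 1], got {cos_incident}")
    return _fresnel(n1, n2, cos_incident)


@njit(cache=True)
def _fresnel(n1, n2, ci):
    if n1 == n2:
        return 0.0, ci
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 / n2 * si
    if st >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st * st)
    if si < 1e-6:  # normal incidence limit
        r = (n1 - n2) / (n1 + n2)
        return r * r, ct
    # sin/cos addition forms of the unpolarized average
    s_im = si * ct - ci * st   # sin(i - t)
    s_ip = si * ct + ci * st   # sin(i + t)
    c_im = ci * ct + si * st   # cos(i - t)
    c_ip = ci * ct - si * st   # cos(i + t)
    rs = (s_im / s_ip) ** 2
    rp = (s_im * c_ip / (s_ip * c_im)) ** 2
    return 0.5 * (rs + rp), ct


@njit(cache=True)
def _hg_cos(g, u):
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _mc_kernel(mu_a, mu_s, g, nidx, z_if, n_top, n_bot, fresnel_mode,
               n_photons, seed, dr, dz, nr, nz):
    np.random.seed(seed)
    n_layers = mu_a.size
    a_grid = np.zeros((nr, nz))
    a_layer = np.zeros(n_layers)
    rd = 0.0
    tt = 0.0
    absorbed = 0.0

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        w = 1.0
        if fresnel_mode:
            rsp, _ct = _fresnel(n_top, nidx[0], 1.0)
            rd += rsp
            w -= rsp
        s = 0.0
        alive = True
        while alive:
            if s <= 0.0:
                s = -math.log(np.random.random() + 1e-300)
            mu_t = mu_a[layer] + mu_s[layer]
            if uz > 0.0:
                db = (z_if[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z_if[layer] - z) / uz
            else:
                db = 1e30
            step = s / mu_t if mu_t > 0.0 else 1e30
            if db <= step:
                # move to the boundary, carry the unused step fraction
                x += ux * db
                y += uy * db
                z += uz * db
                s -= db * mu_t
                going_down = uz > 0.0
                if fresnel_mode:
                    n1 = nidx[layer]
                    if going_down:
                        n2 = nidx[layer + 1] if layer + 1 < n_layers else n_bot
                    else:
                        n2 = nidx[layer - 1] if layer > 0 else n_top
                    rprob, ct = _fresnel(n1, n2, abs(uz))
                    if np.random.random() < rprob:
                        uz = -uz
                        continue
                    # refract
                    scale = n1 / n2
                    ux *= scale
                    uy *= scale
                    uz = ct if going_down else -ct
                if going_down:
                    if layer + 1 < n_layers:
                        layer += 1
                    else:
                        tt += w
                        alive = False
                else:
                    if layer > 0:
                        layer -= 1
                    else:
                        rd += w
                        alive = False
            else:
                x += ux * step
                y += uy * step
                z += uz * step
                s = 0.0
                # absorb
                dw = w * mu_a[layer] / mu_t
                if dw > 0.0:
                    r = math.sqrt(x * x + y * y)
                    ir = int(r / dr)
                    if ir > nr - 1:
                        ir = nr - 1
                    iz = int(z / dz)
                    if iz > nz - 1:
                        iz = nz - 1
                    elif iz < 0:
                        iz = 0
                    a_grid[ir, iz] += dw
                    a_layer[layer] += dw
                    absorbed += dw
                    w -= dw
                # scatter
                ct = _hg_cos(g[layer], np.random.random())
                st = math.sqrt(max(0.0, 1.0 - ct * ct))
                phi = 2.0 * math.pi * np.random.random()
                cp = math.cos(phi)
                sp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz >= 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_n = -st * cp * den + uz * ct
                    ux, uy, uz = ux_n, uy_n, uz_n
                # roulette
                if w < _W_ROULETTE:
                    if np.random.random() < _P_SURVIVE:
                        w /= _P_SURVIVE
                    else:
                        alive = False
    return rd, tt, absorbed, a_grid, a_layer


def run_mc(stack: LayerStack, n_photons: int, seed: int,
           grid: tuple[float, float, int, int] = (0.005, 0.005, 120, 120)) -> MCResult:
    """Run the multilayer Monte-Carlo simulation for a pencil beam.

    Parameters
    ----------
    stack : LayerStack
        The layer geometry and boundary mode.
    n_photons : int
        Number of photon packets (>= 1).
    seed : int
        RNG seed (Mersenne Twister inside the compiled kernel); recorded in
        the result for reproducibility.
    grid : (dr, dz, nr, nz)
        Cylindrical tally grid: radial/axial bin widths (cm) and counts.
        Absorbed weight beyond the last radial bin is folded into it.

    Returns
    -------
    MCResult with R_d, T_t, absorbed fraction, raw absorption grid and the
    fluence-rate grid ``phi = A / (mu_a dV N)`` (cm^-2 per unit incident
    power).  Bins lying in a non-absorbing layer have undefined fluence by
    this estimator and are reported as 0.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    dr, dz, nr, nz = grid
    if dr <= 0 or dz <= 0 or nr < 1 or nz < 1:
        raise ValueError(f"grid must be positive, got {grid}")
    for i, lay in enumerate(stack.layers):
        if lay.mu_a + lay.mu_s == 0.0:
            raise ValueError(
                f"layer {i} has mu_a + mu_s = 0: infinite free path is not "
                "supported (no interaction can terminate the walk)"
            )
    mu_a = np.array([l.mu_a for l in stack.layers])
    mu_s = np.array([l.mu_s for l in stack.layers])
    g = np.array([l.g for l in stack.layers])
    nidx = np.array([l.n for l in stack.layers])
    z_if = stack.interfaces
    rd, tt, absorbed, a_grid, a_layer = _mc_kernel(
        mu_a, mu_s, g, nidx, z_if, stack.ambient_n_top, stack.ambient_n_bottom,
        stack.boundary_mode == "fresnel", int(n_photons), int(seed),
        float(dr), float(dz), int(nr), int(nz),
    )
    # fluence conversion: phi = A / (mu_a(z) * dV * N)
    ir = np.arange(nr)
    dV = 2.0 * math.pi * (ir + 0.5) * dr * dr * dz  # shell volumes, cm^3
    z_centers = (np.arange(nz) + 0.5) * dz
    mu_a_of_z = np.zeros(nz)
    for iz, zc in enumerate(z_centers):
        layer = int(np.searchsorted(z_if[1:-1], zc, side="right"))
        layer = min(layer, len(stack.layers) - 1)
        mu_a_of_z[iz] = stack.layers[layer].mu_a
    with np.errstate(divide="ignore", invalid="ignore"):
        fluence = a_grid / (mu_a_of_z[None, :] * dV[:, None] * n_photons)
    fluence[:, mu_a_of_z == 0.0] = 0.0
    return MCResult(
        R_d=rd / n_photons,
        T_t=tt / n_photons,
        absorbed=absorbed / n_photons,
        fluence=fluence,
        absorption_grid=a_grid / n_photons,
        absorbed_by_layer=a_layer / n_photons,
        n_photons=int(n_photons),
        seed=int(seed),
        grid=(float(dr), float(dz), int(nr), int(nz)),
        r_edges=np.arange(nr + 1) * dr,
        z_edges=np.arange(nz + 1) * dz,
    )


# anatomical thicknesses of the head model layers, cm (skin, skull, brain)
HEAD_THICKNESSES = {"skin": 0.11, "skull": 0.10, "brain": 0.30}


def three_layer_fluence(wavelength: float, n_photons: int = 100_000, seed: int = 0,
                        boundary_mode: str = "matched",
                        grid: tuple[float, float, int, int] = (0.005, 0.005, 120, 120),
                        ) -> MCResult:
    """Fluence map in the skin/skull/brain head model at one wavelength.

    Builds the three-layer stack (thicknesses 0.11, 0.10, 0.30 cm) from the
    tissue presets at the requested wavelength and runs :func:`run_mc`.
    """
    from tissueoptics.synthetic_data import PRESET_WAVELENGTHS, make_preset

    if wavelength not in PRESET_WAVELENGTHS:
        raise ValueError(
            f"no presets at {wavelength} nm; available: {sorted(PRESET_WAVELENGTHS)}"
        )
    layers = []
    for tissue in ("skin", "skull", "brain"):
        p = make_preset(tissue, wavelength).properties
        layers.append(Layer(mu_a=p.mu_a, mu_s=p.mu_s, g=p.g, n=p.n,
                            thickness=HEAD_THICKNESSES[tissue]))
    stack = LayerStack(layers, boundary_mode=boundary_mode)
    return run_mc(stack, n_photons=n_photons, seed=seed, grid=grid)
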