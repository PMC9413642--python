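"""End-to-end orchestration: measurements -> inversion -> fits -> fluence.

`run_pipeline` chains the package stages exactly as the analysis does:

1. synthesize (or load) integrating-sphere measurements per tissue and
   wavelength;
2. invert them through the Kubelka-Munk model into mu_a and mu_s', derive
   mu_s from the collimated transmittance, g from the two scattering
   coefficients, and n from the refractometer series;
3. compute penetration depths;
4. run the three-layer Monte-Carlo fluence maps per wavelength;
5. solve the FEM diffusion problem per tissue/wavelength and export the
   surface fluence profiles;
6. write a JSON manifest with every seed and setting so a run is exactly
   reproducible from its saved config.

All randomness flows from one master seed, split per stage with
numpy's SeedSequence.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from tissueoptics import io
from tissueoptics.diffusion_fem import (
    DiffusionProblem,
    build_mesh,
    solve_fluence,
    surface_fluence_map,
)
from tissueoptics.dispersion import anisotropy_from_scattering, mus_from_collimated
from tissueoptics.kubelka_munk import (
    km_inverse,
    km_to_optical,
    penetration_depth,
)
from tissueoptics.mc_transport import three_layer_fluence
from tissueoptics.synthetic_data import (
    PRESET_TISSUES,
    PRESET_WAVELENGTHS,
    generate_refractometer_series,
    generate_sphere_measurements,
    make_preset,
)

_log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    out_dir: str
    tissues: tuple[str, ...] = PRESET_TISSUES
    wavelengths: tuple[int, ...] = PRESET_WAVELENGTHS
    noise_sd: float = 0.0
    engine: str = "km"
    thickness_convention: str = "spectral"  # spectral (0.5 mm) | anatomical
    master_seed: int = 0
    mc_photons: int = 100_000
    mc_grid: tuple[float, float, int, int] = (0.005, 0.005, 120, 120)
    fem_h: float = 0.02
    fem_boundary: str = "robin"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for t in self.tissues:
            if t not in PRESET_TISSUES:
                raise ValueError(f"unknown tissue {t!r}")
        for w in self.wavelengths:
            if w not in PRESET_WAVELENGTHS:
                raise ValueError(f"unknown wavelength {w}")
        if self.thickness_convention not in ("spectral", "anatomical"):
            raise ValueError("thickness_convention must be spectral|anatomical")
        if self.engine not in ("km", "mc"):
            raise ValueError("engine must be km|mc")
        if self.noise_sd < 0 or self.mc_photons < 1 or self.fem_h <= 0:
            raise ValueError("invalid numeric settings")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        obj = json.loads(text)
        obj["tissues"] = tuple(obj["tissues"])
        obj["wavelengths"] = tuple(obj["wavelengths"])
        obj["mc_grid"] = tuple(obj["mc_grid"])
        return cls(**obj)


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    """Split a master seed into per-stage integer seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write tables, grids, profiles, and a manifest.

    Returns the manifest dict.  Any stage failure aborts with the stage name
    and the offending tissue/wavelength in the exception message.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed, 3)
    seed_measure, seed_mc, seed_refr = seeds

    # Stage 1-2: measurements -> optical properties
    props, tissues_col, depths = [], [], []
    for tissue in config.tissues:
        try:
            readings = generate_refractometer_series(
                tissue, noise_sd=0.0 if config.noise_sd == 0 else 0.0002,
                seed=seed_refr,
            )
            n_by_wl = {r.wavelength: r.recovered_n() for r in readings}
        except Exception as exc:
            raise RuntimeError(f"stage refractometer failed for {tissue}: {exc}") from exc
        for wl in config.wavelengths:
            try:
                preset = make_preset(tissue, wl)
                d = (preset.slab_thickness_spectral
                     if config.thickness_convention == "spectral"
                     else preset.anatomical_thickness)
                ms = generate_sphere_measurements(
                    preset, noise_sd=config.noise_sd, seed=seed_measure,
                    engine=config.engine, thickness=d,
                )
                rec = ms.records[0]
                coeffs = km_inverse(rec)
                mu_a = coeffs.A_km / 2.0
                mu_s = mus_from_collimated(rec.T_c, rec.d, mu_a)
                opt = km_to_optical(coeffs, g=0.0, wavelength=wl)
                g = anisotropy_from_scattering(min(opt.mu_s_reduced, mu_s), mu_s)
                p = km_to_optical(coeffs, g=g, wavelength=wl,
                                  n=n_by_wl.get(float(wl), 1.0))
                props.append(p)
                tissues_col.append(tissue)
                depths.append(penetration_depth(p.mu_a, p.mu_s_reduced)
                              if p.mu_a > 0 else math.inf)
            except Exception as exc:
                raise RuntimeError(
                    f"stage inversion failed for {tissue}@{wl}nm: {exc}"
                ) from exc
    io.write_properties_table(
        out / "optical_properties.csv", props, tissues=tissues_col,
        extra={"penetration_depth_cm": depths},
    )

    # Stage 4: three-layer MC fluence per wavelength
    mc_summaries = {}
    for wl in config.wavelengths:
        try:
            res = three_layer_fluence(
                wl, n_photons=config.mc_photons, seed=seed_mc,
                grid=config.mc_grid,
            )
        except Exception as exc:
            raise RuntimeError(f"stage mc failed at {wl}nm: {exc}") from exc
        io.write_fluence_grid(
            out / f"mc_fluence_{wl}nm.csv", out / f"mc_fluence_{wl}nm.json",
            res.fluence, res.grid,
            meta={"wavelength_nm": wl, "n_photons": res.n_photons,
                  "seed": res.seed},
        )
        mc_summaries[str(wl)] = {
            "R_d": res.R_d, "T_t": res.T_t, "absorbed": res.absorbed,
            "absorbed_by_layer": res.absorbed_by_layer.tolist(),
        }

    # Stage 5: FEM surface fluence per tissue/wavelength
    mesh = build_mesh(config.fem_h)
    for i, p in enumerate(props):
        tissue, wl = tissues_col[i], int(p.wavelength)
        try:
            prob = DiffusionProblem(mu_a=p.mu_a, mu_s_reduced=p.mu_s_reduced,
                                    boundary=config.fem_boundary)
            s, phi_b = surface_fluence_map(solve_fluence(prob, mesh))
        except Exception as exc:
            raise RuntimeError(f"stage fem failed for {tissue}@{wl}nm: {exc}") from exc
        np.savetxt(out / f"fem_surface_{tissue}_{wl}nm.csv",
                   np.column_stack([s, phi_b]), delimiter=",",
                   header="arclength_cm,fluence", comments="")

    manifest = {
        "config": dataclasses.asdict(config),
        "stage_seeds": {"measurements": seed_measure, "mc": seed_mc,
                        "refractometer": seed_refr},
        "mc_summaries": mc_summaries,
        "outputs": sorted(f.name for f in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
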