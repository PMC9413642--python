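"""Readers and writers for the package's table and config dialects.

Measurement tables, derived property tables and fluence grids are plain CSV
(dot decimal separator, no locale dependence); layer stacks and run
manifests are JSON or YAML; fit results are JSON records.  Thicknesses in
measurement tables are millimetres (the bench convention) and are converted
to centimetres exactly once, here.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from tissueoptics.kubelka_munk import OpticalProperties, SlabMeasurement
from tissueoptics.mc_transport import Layer, LayerStack

_log = logging.getLogger(__name__)

__all__ = [
    "read_measurement_table",
    "write_measurement_table",
    "read_properties_table",
    "write_properties_table",
    "read_layer_stack",
    "write_layer_stack",
    "write_fluence_grid",
    "read_fluence_grid",
    "write_fit_result",
]

MM_TO_CM = 0.1


def read_measurement_table(path) -> list[SlabMeasurement]:
    """Read a CSV of sphere measurements.

    Required columns: ``wavelength_nm``, ``Rd``, ``thickness_mm`` and either
    ``Td`` or ``Tt`` (optionally with ``Tc``).  When only ``Tt`` is present,
    ``Td = Tt - Tc`` with ``Tc`` defaulting to 0 under a logged warning (the
    ballistic component is then attributed to the diffuse channel).
    Malformed rows are reported with their line number.
    """
    df = pd.read_csv(path)
    required = {"wavelength_nm", "Rd", "thickness_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "Td" not in df.columns and "Tt" not in df.columns:
        raise ValueError(f"{path}: need a 'Td' or 'Tt' column")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            d = float(row["thickness_mm"]) * MM_TO_CM
            tt = float(row["Tt"]) if "Tt" in df.columns and pd.notna(row.get("Tt")) else None
            tc = float(row["Tc"]) if "Tc" in df.columns and pd.notna(row.get("Tc")) else None
            if "Td" in df.columns and pd.notna(row.get("Td")):
                td = float(row["Td"])
            else:
                if tc is None:
                    _log.warning(
                        "%s line %d: no Tc column; using Td = Tt with Tc = 0",
                        path, line,
                    )
                    tc_eff = 0.0
                else:
                    tc_eff = tc
                td = tt - tc_eff
            records.append(SlabMeasurement(
                wavelength=float(row["wavelength_nm"]), R_d=float(row["Rd"]),
                T_d=td, d=d, T_t=tt, T_c=tc,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line}: {exc}") from exc
    return records


def write_measurement_table(path, records: list[SlabMeasurement]) -> None:
    rows = []
    for m in records:
        rows.append({
            "wavelength_nm": m.wavelength, "Rd": m.R_d, "Td": m.T_d,
            "Tt": m.T_t if m.T_t is not None else "",
            "Tc": m.T_c if m.T_c is not None else "",
            "thickness_mm": m.d / MM_TO_CM,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_properties_table(path, props, tissues=None, extra=None) -> None:
    """Write derived optical properties keyed by wavelength (and tissue).

    ``extra`` maps column name -> sequence (e.g. penetration depth).
    """
    rows = []
    for i, p in enumerate(props):
        row = {
            "wavelength_nm": p.wavelength, "mu_a_cm1": p.mu_a,
            "mu_s_reduced_cm1": p.mu_s_reduced, "g": p.g, "n": p.n,
        }
        if p.mu_s is not None:
            row["mu_s_cm1"] = p.mu_s
        if tissues is not None:
            row = {"tissue": tissues[i], **row}
        if extra:
            for k, v in extra.items():
                row[k] = v[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_properties_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"wavelength_nm", "mu_a_cm1", "mu_s_reduced_cm1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def write_layer_stack(path, stack: LayerStack) -> None:
    obj = {
        "boundary_mode": stack.boundary_mode,
        "ambient_n_top": stack.ambient_n_top,
        "ambient_n_bottom": stack.ambient_n_bottom,
        "layers": [
            {"mu_a": l.mu_a, "mu_s": l.mu_s, "g": l.g, "n": l.n,
             "thickness": l.thickness}
            for l in stack.layers
        ],
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=1))


def read_layer_stack(path) -> LayerStack:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        obj = yaml.safe_load(path.read_text())
    else:
        obj = json.loads(path.read_text())
    layers = [Layer(**rec) for rec in obj["layers"]]
    return LayerStack(
        layers,
        ambient_n_top=obj.get("ambient_n_top", 1.0),
        ambient_n_bottom=obj.get("ambient_n_bottom", 1.0),
        boundary_mode=obj.get("boundary_mode", "matched"),
    )


def write_fluence_grid(csv_path, json_path, fluence: np.ndarray,
                       grid: tuple[float, float, int, int], meta=None) -> None:
    """Fluence matrix as CSV (rows = radial bins) plus a JSON axis spec."""
    np.savetxt(csv_path, fluence, delimiter=",")
    dr, dz, nr, nz = grid
    spec = {"dr_cm": dr, "dz_cm": dz, "nr": nr, "nz": nz,
            "rows": "radial bins (r = (i+0.5) dr)",
            "cols": "depth bins (z = (j+0.5) dz)"}
    if meta:
        spec.update(meta)
    Path(json_path).write_text(json.dumps(spec, indent=1))


def read_fluence_grid(csv_path, json_path):
    spec = json.loads(Path(json_path).read_text())
    grid = np.loadtxt(csv_path, delimiter=",")
    return grid, spec


def write_fit_result(path, model: str, params: dict, residual_norm: float) -> None:
    Path(path).write_text(json.dumps(
        {"model": model, "parameters": params, "residual_norm": residual_norm},
        indent=1,
    ))
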