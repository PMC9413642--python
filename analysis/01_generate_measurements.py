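#!/usr/bin/env python
"""Synthesize the integrating-sphere and refractometer measurement sets.

Emulates the bench campaign: for each tissue (skin, skull, brain) and laser
wavelength (532, 660, 785, 980 nm), a 0.5 mm slab is "measured" for diffuse
reflectance, diffuse/total transmittance and collimated transmittance, both
noiseless and with 1% multiplicative noise; Abbe critical-angle readings are
generated per tissue at 2e-4 RI accuracy.  Writes CSV measurement tables
under results/measurements/.
"""

import json
from pathlib import Path

from tissueoptics import io
from tissueoptics.synthetic_data import (
    PRESET_TISSUES,
    PRESET_WAVELENGTHS,
    generate_refractometer_series,
    generate_sphere_measurements,
    make_preset,
)

SEED = 20220818
OUT = Path(__file__).resolve().parent.parent / "results" / "measurements"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for noise, tag in ((0.0, "noiseless"), (0.01, "noisy1pct")):
        for tissue in PRESET_TISSUES:
            records = []
            for i, wl in enumerate(PRESET_WAVELENGTHS):
                ms = generate_sphere_measurements(
                    make_preset(tissue, wl), noise_sd=noise,
                    seed=SEED + 100 * i, engine="km",
                )
                records.extend(ms.records)
            io.write_measurement_table(OUT / f"sphere_{tissue}_{tag}.csv", records)
    for tissue in PRESET_TISSUES:
        readings = generate_refractometer_series(tissue, noise_sd=2e-4, seed=SEED)
        (OUT / f"refractometer_{tissue}.json").write_text(json.dumps(
            [{"wavelength_nm": r.wavelength,
              "critical_angle_deg": r.critical_angle_deg,
              "prism_n": r.prism_n, "noise_sd": r.noise_sd}
             for r in readings], indent=1))
    print(f"wrote sphere tables (noiseless + 1% noise) and refractometer "
          f"series for {len(PRESET_TISSUES)} tissues to {OUT}")


if __name__ == "__main__":
    main()
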