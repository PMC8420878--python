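"""Generate the bundled synthetic optical-property tables.

The chromophore compilations cited for the skin model (whole-blood Hb/HbO2,
bilirubin, cytochrome c oxidase) and the measured phantom ingredient curves
(clear SiliGlass medium, diluted pigment, SEM microsphere size distribution)
are not deposited anywhere machine-readable. This script builds smooth,
plausible stand-ins: Gaussian band models with peak positions and magnitudes
of the right class, and a bimodal lognormal sphere-volume distribution whose
effective index is calibrated so the recipe concentrations land in the
documented reduced-scattering regime. Files are written once into
``src/hsicurve/data/`` and shipped with the package; every filename carries the
``synthetic_`` prefix.

Run from the repository root: ``python scripts/make_tables.py``.
"""

import json
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "hsicurve" / "data"

LAM = np.arange(400.0, 751.0, 1.0)


def G(center, width):
    return np.exp(-0.5 * ((LAM - center) / width) ** 2)


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    # --- whole-blood hemoglobin (volume fraction 1), cm^-1 ---
    hb = 400.0 * G(430, 18) + 60.0 * G(556, 20) + 30.0 * G(525, 40) + 3.5
    hbo2 = (
        500.0 * G(414, 14)
        + 45.0 * G(542, 13)
        + 48.0 * G(577, 11)
        + 20.0 * G(520, 35)
        + 1.0
    )
    # --- bilirubin, cm^-1 per mM ---
    bil = 120.0 * G(460, 32)
    # --- cytochrome c oxidase, cm^-1 per mM ---
    cyt_red = 270.0 * G(445, 15) + 28.0 * G(605, 13) + 12.0 * G(520, 25)
    cyt_ox = 180.0 * G(425, 20) + 3.0 * G(655, 60) + 8.0 * G(830, 120)

    # sanity: positive, and Hb/HbO2 cross somewhere in the fitting window
    assert np.all(hb > 0) and np.all(hbo2 > 0)
    d = hb - hbo2
    sel = (LAM >= 430) & (LAM <= 700)
    assert np.any(np.diff(np.sign(d[sel])) != 0), "need isosbestic crossings"

    def write(name, cols):
        header = ",".join(["wavelength_nm"] + list(cols))
        data = np.column_stack([LAM] + [cols[c] for c in cols])
        np.savetxt(OUT / name, data, delimiter=",", header=header, comments="", fmt="%.6g")

    write("synthetic_hemoglobin.csv", {"mua_Hb_cm1": hb, "mua_HbO2_cm1": hbo2})
    write("synthetic_bilirubin.csv", {"mua_bil_cm1_per_mM": bil})
    write(
        "synthetic_cytochrome.csv",
        {"mua_CytO_cm1_per_mM": cyt_red, "mua_CytOO2_cm1_per_mM": cyt_ox},
    )

    # --- phantom ingredient absorption, cm^-1 ---
    # clear polymerized medium: weak, falling toward the red
    mu_ab = 0.022 + 0.09 * np.exp(-(LAM - 400.0) / 70.0)
    # diluted pigment at the 5.83e-5 measurement mass fraction: nearly flat
    mu_abs = 0.37 - 6.0e-5 * (LAM - 430.0) + 0.005 * np.exp(-(LAM - 400.0) / 90.0)
    assert np.all(mu_ab > 0) and np.all(mu_abs > 0)
    write("synthetic_siliglass.csv", {"mua_AB_cm1": mu_ab, "mua_abs_cm1": mu_abs})

    # --- microsphere volume-fraction distribution ---
    radii = np.concatenate([np.arange(1.0, 3.0, 0.25), np.arange(3.0, 16.01, 0.5)])
    main_mode = np.exp(-0.5 * ((np.log(radii) - np.log(7.0)) / 0.4) ** 2)
    fines = np.exp(-0.5 * ((np.log(radii) - np.log(1.3)) / 0.3) ** 2)
    w_fines = 0.35
    phi = (1.0 - w_fines) * main_mode / main_mode.sum() + w_fines * fines / fines.sum()
    phi /= phi.sum()
    np.savetxt(
        OUT / "synthetic_spheres.csv",
        np.column_stack([radii, phi]),
        delimiter=",",
        header="radius_um,volume_fraction",
        comments="",
        fmt="%.6g",
    )

    config = {
        "description": "SiliGlass phantom recipe constants and synthetic-table metadata",
        "dilution_denominator": 0.13246,
        "predilution_ratio": 2272,
        "wall_loss_g": 1.0,
        "thickness_cm": 2.0,
        "sphere_index": 1.65,
        "cab_subtract_scatterer": False,
        "provenance": "synthetic band-model compilations generated by scripts/make_tables.py",
    }
    (OUT / "phantom_config.json").write_text(json.dumps(config, indent=2) + "\n")
    print("wrote tables to", OUT)


if __name__ == "__main__":
    main()
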