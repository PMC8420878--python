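"""Vascular-occlusion-test phases of the two-layer skin model.

Prints the hemodynamic parameters of the three VOT phases and the forward
reflectance they imply; the occlusion raises deoxyhemoglobin, the release
overshoots oxyhemoglobin while melanin never changes.
"""

import numpy as np

from hsicurve import ForwardModel
from hsicurve.optics import default_wavelength_grid
from hsicurve.synthetic import vot_phase_params

grid = default_wavelength_grid()
fm = ForwardModel("skin", grid)

print(f"{'phase':8s} {'fmel %':>7s} {'fHb %':>7s} {'fHbO2 %':>8s} {'StO2':>6s} {'R(560nm)':>9s}")
for phase in ("before", "during", "after"):
    p = vot_phase_params(phase)
    r = fm.reflectance(p.free_values())
    r560 = float(np.interp(560.0, grid, r))
    print(f"{phase:8s} {p.fmel:7.2f} {p.fHb:7.2f} {p.fHbO2:8.2f} "
          f"{p.oxygen_saturation:6.2f} {r560:9.4f}")

print("  -> oxygen saturation dips during cuff inflation and overshoots after release;")
print("  R(560 nm) is lowest during occlusion, where the deoxyhemoglobin band absorbs strongest")
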