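"""Inverse round trip: recover phantom concentrations from a spectrum.

A reflectance spectrum is generated for known absorber/scatterer volume
fractions, then inverted with the bounded Levenberg-Marquardt fit seeded by
the multi-start initializer.
"""

import numpy as np

from hsicurve import FitConfig, ForwardModel, fit_spectrum, multistart_init

cfg = FitConfig(model="phantom", seed=3, n_starts=16, max_iterations=60)
fm = ForwardModel("phantom", cfg.grid(), cfg)

truth = np.array([3.7, 1.6])  # Cabs %, Csc %
spectrum = fm.reflectance(truth)
print(f"forward spectrum over {fm.grid.size} bands, R = {spectrum.min():.3f}..{spectrum.max():.3f}")

init = multistart_init(spectrum[None, :], fm, cfg)
result = fit_spectrum(spectrum, fm, cfg, init=init)
print(f"multistart init: Cabs = {init[0]:.2f}%, Csc = {init[1]:.2f}%")
print(f"fitted:          Cabs = {result.params[0]:.3f}%, Csc = {result.params[1]:.3f}%  "
      f"(truth 3.700 / 1.600), R^2 = {result.r_squared:.6f}")
err = np.abs(result.params / truth - 1).max() * 100
print(f"  -> worst relative error {err:.3f}%: the two phantom parameters are fully identifiable")

# an uncorrected 60-degree tilt scales the spectrum by cos(60) = 0.5
biased = fit_spectrum(spectrum * 0.5, fm, cfg, init=truth)
print(f"same spectrum x cos(60 deg): Cabs = {biased.params[0]:.1f}% "
      f"-> unremoved shading inflates the fitted absorption, the artifact the correction exists to prevent")
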