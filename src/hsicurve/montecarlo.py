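"""Monte Carlo photon transport in a layered slab.

An independent reference for the adding-doubling solver: weighted photon
packets, Henyey-Greenstein scattering, Fresnel boundaries with refraction
between layers and at the outer interfaces, Russian roulette. Geometry and
illumination match the solver: collimated normal incidence, first-surface
specular reflection excluded (packets start inside with weight ``1 - r_s``),
diffuse reflectance and transmittance tallied as escaping weight.

Only 1-D (infinite transverse extent) is tracked, which is all the slab
comparison needs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .optics import LayerOpticalProperties

__all__ = ["mc_reflectance"]


@njit(cache=True)
def _fresnel(n1, n2, mu):
    """Unpolarized Fresnel reflectance; returns (r, mu_t)."""
    if n1 == n2:
        return 0.0, mu
    sin_t2 = (n1 / n2) ** 2 * (1.0 - mu * mu)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    mu_t = np.sqrt(1.0 - sin_t2)
    rs = ((n1 * mu - n2 * mu_t) / (n1 * mu + n2 * mu_t)) ** 2
    rp = ((n1 * mu_t - n2 * mu) / (n1 * mu_t + n2 * mu)) ** 2
    return 0.5 * (rs + rp), mu_t


@njit(cache=True)
def _run(mua, mus, g, n, z_bound, n_out, n_photons, seed):
    np.random.seed(seed)
    n_layers = mua.shape[0]
    refl = 0.0
    trans = 0.0
    absorbed = 0.0
    w_min = 1e-4
    for _ in range(n_photons):
        r_spec, _ = _fresnel(n_out, n[0], 1.0)
        w = 1.0 - r_spec
        layer = 0
        z = 0.0
        uz = 1.0
        alive = True
        left = 0.0  # dimensionless path left from previous step (none)
        while alive:
            mut = mua[layer] + mus[layer]
            s = -np.log(np.random.random() + 1e-300)
            # propagate, crossing boundaries as needed
            while True:
                if mut > 0.0:
                    step = s / mut
                else:
                    step = 1.0e9
                if uz > 0.0:
                    db = (z_bound[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bound[layer] - z) / uz
                else:
                    db = 1.0e9
                if db < step:
                    # hit a layer boundary
                    s -= db * mut
                    z = z_bound[layer + 1] if uz > 0.0 else z_bound[layer]
                    going_down = uz > 0.0
                    if going_down:
                        n1 = n[layer]
                        n2 = n[layer + 1] if layer + 1 < n_layers else n_out
                    else:
                        n1 = n[layer]
                        n2 = n[layer - 1] if layer > 0 else n_out
                    r, mu_t = _fresnel(n1, n2, abs(uz))
                    if np.random.random() > r:
                        # transmit
                        if going_down:
                            if layer + 1 < n_layers:
                                layer += 1
                                uz = mu_t
                            else:
                                trans += w
                                alive = False
                                break
                        else:
                            if layer > 0:
                                layer -= 1
                                uz = -mu_t
                            else:
                                refl += w
                                alive = False
                                break
                        # rescale remaining optical path in the new layer
                        continue
                    else:
                        uz = -uz
                        continue
                else:
                    z += step * uz
                    break
            if not alive:
                break
            # absorb and scatter
            if mut > 0.0:
                da = w * mua[layer] / mut
                absorbed += da
                w -= da
            gl = g[layer]
            if mus[layer] > 0.0:
                if gl != 0.0:
                    tmp = (1.0 - gl * gl) / (1.0 - gl + 2.0 * gl * np.random.random())
                    ct = (1.0 + gl * gl - tmp * tmp) / (2.0 * gl)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                else:
                    ct = 2.0 * np.random.random() - 1.0
                # azimuthal symmetry: only the polar direction matters in 1-D
                st = np.sqrt(1.0 - ct * ct)
                phi = 2.0 * np.pi * np.random.random()
                sz = np.sqrt(max(1.0 - uz * uz, 0.0))
                uz = -st * np.cos(phi) * sz + ct * uz
                if uz > 1.0:
                    uz = 1.0
                elif uz < -1.0:
                    uz = -1.0
            else:
                # pure absorber: keep direction
                pass
            if w < w_min:
                if np.random.random() < 0.1:
                    w *= 10.0
                else:
                    absorbed += w
                    alive = False
    return refl, trans, absorbed


def mc_reflectance(
    layers: list[LayerOpticalProperties],
    n_outside: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 1,
) -> tuple[float, float, float]:
    """Diffuse reflectance, transmittance and their common standard error.

    Scalar optical properties only (one wavelength at a time). The returned
    standard error is the binomial estimate ``sqrt(R(1-R)/N)`` on reflectance.
    """
    mua = np.array([float(np.asarray(l.mua).ravel()[0]) for l in layers])
    mus = np.array([float(np.asarray(l.mus).ravel()[0]) for l in layers])
    g = np.array([float(np.asarray(l.g).ravel()[0]) for l in layers])
    n = np.array([float(np.asarray(l.n).ravel()[0]) for l in layers])
    thick = np.array([float(l.thickness) for l in layers])
    z_bound = np.concatenate([[0.0], np.cumsum(thick)])
    refl, trans, _ = _run(mua, mus, g, n, z_bound, float(n_outside), int(n_photons), int(seed))
    R = refl / n_photons
    T = trans / n_photons
    se = float(np.sqrt(max(R * (1.0 - R), 1e-12) / n_photons))
    return float(R), float(T), se
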