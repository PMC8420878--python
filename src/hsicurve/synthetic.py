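"""Synthetic scenes: registered (cube, height map, truth, normals) quadruples.

Stands in for the instrument: a geometric surface (hemisphere, tilted plane,
or finger-like cylinder) is populated with material parameters, per-pixel
reflectance spectra come from the adding-doubling forward model, and the two
artifacts the correction pipeline targets are applied in closed form:

* Lambert shading - multiply by ``cos(theta)`` of the analytic surface normal
  against vertical illumination;
* distance falloff - multiply by ``P(d)/P(d_work)`` for a configured quadratic
  falloff ``P`` (an inverse-square law fitted over the calibration span).

Optionally multiplicative noise, profilometry height noise, laser-shadow holes
and a deliberately *uncorrectable* additive interreflection term (concave
regions receive extra ambient light; the cosine correction cannot remove an
additive contribution) are added. Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .correction import HeightCalibration, fit_height_calibration
from .datacube import HeightMap, ReflectanceCube
from .inversion import ForwardModel, ParameterMap
from .optics import PhantomParams, SkinParams, default_wavelength_grid
from .surface import NormalField, VERTICAL_ILLUMINATION

__all__ = [
    "SceneSpec",
    "generate_scene",
    "vot_phase_params",
    "inverse_square_calibration",
]


def inverse_square_calibration(
    working_distance: float = 300.0,
    span: float = 20.0,
    n_distances: int = 9,
    n_bands: int = 1,
) -> HeightCalibration:
    """Quadratic calibration of an inverse-square intensity falloff.

    Emulates imaging a white standard at ``n_distances`` heights within
    ``+-span`` mm of the working distance; the quadratic fit residual is well
    under 1% of the mean over that range.
    """
    d = np.linspace(working_distance - span, working_distance + span, n_distances)
    intensity = (working_distance / d) ** 2
    I = np.tile(intensity[:, None], (1, n_bands))
    return fit_height_calibration(d, I, working_distance, per_band=n_bands > 1)


@dataclass
class SceneSpec:
    """Geometry, material, artifact switches and noise levels of a scene."""

    geometry: Literal["hemisphere", "plane", "cylinder"] = "hemisphere"
    radius: float = 15.0  # mm, hemisphere/cylinder
    tilt: float = 0.0  # deg, plane tilt about the column axis
    shape: tuple[int, int] = (48, 48)
    pixel_pitch: float = 0.7  # mm/pixel
    material: PhantomParams | SkinParams = field(default_factory=lambda: PhantomParams(3.7, 1.6))
    material_map: np.ndarray | None = None  # optional (ni, nj, n_free) truth override
    lambert_artifact: bool = True
    height_artifact: bool = True
    interreflection: float = 0.0  # additive ambient fraction in concave regions
    noise_sigma: float = 0.0  # multiplicative Gaussian on the cube
    height_noise_sigma: float = 0.0  # mm, profilometry noise
    hole_fraction: float = 0.0  # fraction of height pixels shadowed
    working_distance: float = 300.0
    calibration: HeightCalibration | None = None
    wavelengths: np.ndarray = field(default_factory=default_wavelength_grid)
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.noise_sigma < 0 or self.height_noise_sigma < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def model(self) -> str:
        return "skin" if isinstance(self.material, SkinParams) else "phantom"


def _surface(spec: SceneSpec):
    """Analytic height (mm) and unit normals on the pixel grid."""
    ni, nj = spec.shape
    ii, jj = np.mgrid[0:ni, 0:nj]
    x = (jj - (nj - 1) / 2.0) * spec.pixel_pitch
    y = (ii - (ni - 1) / 2.0) * spec.pixel_pitch
    if spec.geometry == "hemisphere":
        r2 = x**2 + y**2
        cap = r2 < spec.radius**2
        z = np.where(cap, np.sqrt(np.maximum(spec.radius**2 - r2, 0.0)), 0.0)
        n = np.zeros((ni, nj, 3))
        n[..., 2] = 1.0
        n[cap, 0] = x[cap] / spec.radius
        n[cap, 1] = y[cap] / spec.radius
        n[cap, 2] = z[cap] / spec.radius
    elif spec.geometry == "plane":
        t = np.deg2rad(spec.tilt)
        z = x * np.tan(t)
        z -= z.min()
        n = np.zeros((ni, nj, 3))
        n[..., 0] = -np.sin(t)
        n[..., 2] = np.cos(t)
    elif spec.geometry == "cylinder":
        # axis along the rows (scan direction), finger-like
        inside = np.abs(x) < spec.radius
        z = np.where(inside, np.sqrt(np.maximum(spec.radius**2 - x**2, 0.0)), 0.0)
        n = np.zeros((ni, nj, 3))
        n[..., 2] = 1.0
        n[inside, 0] = x[inside] / spec.radius
        n[inside, 2] = z[inside] / spec.radius
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    n /= np.linalg.norm(n, axis=2, keepdims=True)
    return z, n


def generate_scene(spec: SceneSpec):
    """Build the registered quadruple (cube, height map, truth map, normals)."""
    rng = np.random.default_rng(spec.seed)
    z, n = _surface(spec)
    ni, nj = spec.shape
    cos_t = np.clip(n @ VERTICAL_ILLUMINATION, -1.0, 1.0)
    theta = np.rad2deg(np.arccos(cos_t))

    fm = ForwardModel(spec.model, spec.wavelengths)
    names = tuple(type(spec.material).FREE)
    if spec.material_map is not None:
        truth_vals = np.asarray(spec.material_map, dtype=float)
        if truth_vals.shape != (ni, nj, len(names)):
            raise ValueError("material_map shape must be (ni, nj, n_free)")
    else:
        truth_vals = np.tile(spec.material.free_values(), (ni, nj, 1))

    # spectra per unique parameter vector (scenes are piecewise homogeneous)
    flat = truth_vals.reshape(-1, len(names))
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    spectra_uniq = np.stack([fm.reflectance(u) for u in uniq])
    cube_vals = spectra_uniq[inverse].reshape(ni, nj, spec.wavelengths.size)

    if spec.lambert_artifact:
        cube_vals = cube_vals * cos_t[:, :, None]
    cal = spec.calibration
    if spec.height_artifact:
        if cal is None:
            cal = inverse_square_calibration(spec.working_distance)
        dist = spec.working_distance - z
        eps = cal.epsilon(dist)
        cube_vals = cube_vals / eps[:, :, None]
    if spec.interreflection > 0.0:
        concave = _concave_mask(spec, z)
        ambient = spec.interreflection * cube_vals.reshape(-1, spec.wavelengths.size).mean(axis=0)
        cube_vals = cube_vals + concave[:, :, None] * ambient[None, None, :]
    if spec.noise_sigma > 0.0:
        cube_vals = cube_vals * (1.0 + spec.noise_sigma * rng.standard_normal(cube_vals.shape))

    z_meas = z.copy()
    if spec.height_noise_sigma > 0.0:
        z_meas = z_meas + spec.height_noise_sigma * rng.standard_normal(z.shape)
    valid = np.ones((ni, nj), dtype=bool)
    if spec.hole_fraction > 0.0:
        holes = rng.random((ni, nj)) < spec.hole_fraction
        # keep the border valid so harmonic filling stays well posed
        holes[0, :] = holes[-1, :] = holes[:, 0] = holes[:, -1] = False
        z_meas = np.where(holes, np.nan, z_meas)
        valid = ~holes

    cube = ReflectanceCube(
        values=cube_vals,
        wavelengths=spec.wavelengths.copy(),
        pixel_pitch=(spec.pixel_pitch, spec.pixel_pitch),
        working_distance=spec.working_distance,
        provenance={
            "synthetic": True,
            "seed": spec.seed,
            "lambert_artifact": spec.lambert_artifact,
            "height_artifact": spec.height_artifact,
        },
    )
    height = HeightMap(z=z_meas, valid_mask=valid, pixel_pitch=(spec.pixel_pitch, spec.pixel_pitch))
    truth = ParameterMap(
        params={k: truth_vals[:, :, i] for i, k in enumerate(names)},
        r_squared=np.ones((ni, nj)),
        valid=np.ones((ni, nj), dtype=bool),
        meta={"truth": True, "model": spec.model, "seed": spec.seed},
    )
    normals = NormalField(n=n, theta=theta, illumination=VERTICAL_ILLUMINATION.copy())
    return cube, height, truth, normals


def _concave_mask(spec: SceneSpec, z: np.ndarray) -> np.ndarray:
    """Deterministic stand-in for fold/crease regions that see interreflection."""
    if spec.geometry == "hemisphere":
        # the base circle where cap meets tray forms a concave groove
        grad = np.hypot(*np.gradient(z))
        return (z > 0) & (grad > np.percentile(grad[z > 0], 75)) if np.any(z > 0) else z > 0
    if spec.geometry == "cylinder":
        return (z > 0) & (z < 0.3 * spec.radius)
    return np.zeros_like(z, dtype=bool)


_VOT_DEFAULTS = {
    # fmel constant across phases; deoxygenated blood rises during occlusion,
    # oxygenated blood overshoots after cuff release (reactive hyperemia)
    "before": dict(fmel=1.5, fHb=0.5, fHbO2=1.2, fCytO=0.3, fCytOO2=0.3, a=35.0),
    "during": dict(fmel=1.5, fHb=1.5, fHbO2=0.6, fCytO=0.4, fCytOO2=0.2, a=35.0),
    "after": dict(fmel=1.5, fHb=0.3, fHbO2=2.2, fCytO=0.2, fCytOO2=0.4, a=35.0),
}


def vot_phase_params(phase: str, **overrides) -> SkinParams:
    """Skin parameters reproducing the qualitative occlusion-test trends.

    ``before``: resting perfusion; ``during``: cuff inflated, oxygen consumed
    (deoxyhemoglobin up, oxyhemoglobin down); ``after``: reperfusion overshoot
    (oxyhemoglobin well above baseline). Melanin never changes across phases.
    """
    if phase not in _VOT_DEFAULTS:
        raise ValueError(f"unknown VOT phase {phase!r}; expected before/during/after")
    kw = dict(_VOT_DEFAULTS[phase])
    kw.update(overrides)
    return SkinParams(**kw)
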