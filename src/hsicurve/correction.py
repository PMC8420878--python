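"""Height (distance) and Lambert cosine corrections of reflectance cubes.

A curved sample modulates the recorded reflectance in two ways: the
camera-to-surface distance varies with local height (sensor irradiance falls
off with distance), and tilted surface patches receive less irradiance by the
Lambert cosine law. Both are undone per pixel and band:

``I_h = I * eps(lambda)`` with ``eps = P(working distance) / P(actual
distance)`` from a quadratic calibration ``P`` of white-standard intensity
versus distance, followed by ``I_lam = I_h / cos(theta)``.

Distance convention: the camera looks down the +z axis from above, so the
camera-to-surface distance is ``working_distance - z``; higher surfaces are
closer. The Lambert step requires the height step to have run first (tracked
through cube provenance) because the calibration is defined on height-true
intensities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .datacube import HeightMap, ReflectanceCube

__all__ = [
    "HeightCalibration",
    "fit_height_calibration",
    "height_correct",
    "lambert_correct",
    "DEFAULT_MIN_COS",
]

DEFAULT_MIN_COS = 0.1  # cos 84 deg; beyond this 1/cos amplifies noise unboundedly


@dataclass
class HeightCalibration:
    """Quadratic white-standard intensity vs distance, per wavelength band.

    ``coeffs`` has shape ``(n_bands, 3)`` (highest power first, as consumed by
    ``numpy.polyval``); a single row is broadcast over bands (band-averaged
    mode). ``eps(d) = P(working_distance) / P(d)`` equals 1 at the working
    distance by construction.
    """

    coeffs: np.ndarray
    working_distance: float
    distance_range: tuple[float, float]

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape[1] != 3:
            raise ValueError("coefficients must be quadratic (3 per band)")

    def intensity(self, distance, band: int | None = None) -> np.ndarray:
        c = self.coeffs[0] if self.coeffs.shape[0] == 1 or band is None else self.coeffs[band]
        d = np.asarray(distance, dtype=float)
        return c[0] * d**2 + c[1] * d + c[2]

    def epsilon(self, distance, band: int | None = None) -> np.ndarray:
        return self.intensity(self.working_distance, band) / self.intensity(distance, band)

    def to_json(self, path):
        obj = {
            "coeffs": self.coeffs.tolist(),
            "working_distance": self.working_distance,
            "distance_range": list(self.distance_range),
        }
        with open(path, "w") as f:
            json.dump(obj, f, indent=2)

    @classmethod
    def from_json(cls, path) -> "HeightCalibration":
        with open(path) as f:
            obj = json.load(f)
        return cls(
            coeffs=np.asarray(obj["coeffs"]),
            working_distance=float(obj["working_distance"]),
            distance_range=tuple(obj["distance_range"]),
        )


def fit_height_calibration(
    distances: np.ndarray,
    intensities: np.ndarray,
    working_distance: float,
    per_band: bool = True,
) -> HeightCalibration:
    """Least-squares quadratic through mean white-standard intensities.

    ``distances``: (K,) mm; ``intensities``: (K,) band-averaged or (K, n_bands).
    With ``per_band=False`` a single band-averaged polynomial is fit (faster,
    adequate when the falloff is spectrally flat).
    """
    d = np.asarray(distances, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if d.ndim != 1 or np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct calibration distances")
    if I.ndim == 1:
        I = I[:, None]
    if I.shape[0] != d.size:
        raise ValueError("intensity stack does not match distance vector")
    if not per_band:
        I = I.mean(axis=1, keepdims=True)
    coeffs = np.polyfit(d, I, 2).T  # (n_bands, 3)
    cal = HeightCalibration(
        coeffs=coeffs,
        working_distance=float(working_distance),
        distance_range=(float(d.min()), float(d.max())),
    )
    lo, hi = cal.distance_range
    dd = np.linspace(lo, hi, 64)
    fitted = np.array([cal.intensity(dd, b) for b in range(coeffs.shape[0])])
    if np.any(fitted <= 0):
        warnings.warn("fitted calibration polynomial non-positive inside range", stacklevel=2)
    return cal


def height_correct(cube: ReflectanceCube, h: HeightMap, cal: HeightCalibration) -> ReflectanceCube:
    """Rescale each pixel/band by ``eps = P(working) / P(actual distance)``.

    The actual distance is ``cal.working_distance - z``. Pixels outside the
    calibrated distance range are corrected by extrapolation but flagged
    invalid, with a warning. Invalid pixels keep their values untouched.
    """
    if h.shape != cube.shape[:2]:
        raise ValueError("height map grid does not match cube")
    out = cube.copy()
    dist = cal.working_distance - h.z
    valid = cube.valid_mask & h.valid_mask
    lo, hi = cal.distance_range
    inside = (dist >= lo) & (dist <= hi)
    if np.any(valid & ~inside):
        warnings.warn("pixels outside calibrated distance range; flagged invalid", stacklevel=2)
    n_bands = cube.shape[2]
    if cal.coeffs.shape[0] not in (1, n_bands):
        raise ValueError("calibration band count does not match cube")
    if cal.coeffs.shape[0] == 1:
        eps = cal.epsilon(dist)[:, :, None]
    else:
        eps = np.stack([cal.epsilon(dist, b) for b in range(n_bands)], axis=2)
    out.values[valid, :] = cube.values[valid, :] * eps[valid, :]
    out.valid_mask = valid & inside
    out.provenance["height_corrected"] = True
    return out


def lambert_correct(
    cube: ReflectanceCube,
    cos_theta: np.ndarray,
    min_cos: float = DEFAULT_MIN_COS,
    require_height_corrected: bool = True,
) -> ReflectanceCube:
    """Divide out the Lambert cosine factor: ``I_lam = I_h / cos(theta)``.

    Pixels with ``cos(theta) < min_cos`` are masked invalid rather than
    amplified. By default the cube must carry the height-corrected provenance
    flag, enforcing the height-then-Lambert order of the two corrections.
    """
    cos_theta = np.asarray(cos_theta, dtype=float)
    if cos_theta.shape != cube.shape[:2]:
        raise ValueError("cos(theta) field does not match cube grid")
    if require_height_corrected and not cube.provenance.get("height_corrected", False):
        raise ValueError(
            "cube is not height-corrected; run height_correct first "
            "(or pass require_height_corrected=False)"
        )
    out = cube.copy()
    ok = cube.valid_mask & (cos_theta >= min_cos)
    out.values[ok, :] = cube.values[ok, :] / cos_theta[ok, None]
    out.valid_mask = ok
    out.provenance["lambert_corrected"] = True
    out.provenance["min_cos"] = float(min_cos)
    return out
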