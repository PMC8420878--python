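"""Containers for hyperspectral reflectance data, calibration frames and height maps.

Axis convention throughout the package: ``(row i, col j, band)`` where the row
is the scan direction (Y), the column is the sensor line (X) and the band axis
follows the strictly increasing wavelength vector in nanometres. Indices are
0-based and pixel ``(0, 0)`` is the first sample of the first scan line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RawScan",
    "ReflectanceCube",
    "HeightMap",
    "normalize_reflectance",
    "bin_cube",
]


def _as_float(a) -> np.ndarray:
    return np.asarray(a, dtype=np.float64)


@dataclass
class RawScan:
    """Raw pushbroom acquisition: sample, dark and white-standard frames.

    Parameters
    ----------
    raw
        Intensity counts, shape ``(ni, nj, nl)``.
    dark
        Dark-current counts at the same integration time, shape ``(ni, nj)``
        (wavelength-independent detector offset) or ``(ni, nj, nl)``.
    white
        White-standard counts, shape ``(ni, nj, nl)``.
    wavelengths
        Band centres in nm, strictly increasing, length ``nl``.
    """

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    wavelengths: np.ndarray
    pixel_pitch: tuple[float, float] = (0.3, 0.3)
    working_distance: float = 300.0

    def __post_init__(self):
        self.raw = _as_float(self.raw)
        self.dark = _as_float(self.dark)
        self.white = _as_float(self.white)
        self.wavelengths = _as_float(self.wavelengths)
        if self.raw.ndim != 3:
            raise ValueError("raw must be (rows, cols, bands)")
        ni, nj, nl = self.raw.shape
        if self.white.shape != (ni, nj, nl):
            raise ValueError("white frame shape does not match raw")
        if self.dark.shape not in ((ni, nj), (ni, nj, nl)):
            raise ValueError("dark frame shape does not match raw")
        if self.wavelengths.shape != (nl,):
            raise ValueError("wavelength vector length does not match band axis")
        if nl > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def dark3(self) -> np.ndarray:
        """Dark frame broadcast to the full cube shape."""
        if self.dark.ndim == 2:
            return self.dark[:, :, None]
        return self.dark


@dataclass
class ReflectanceCube:
    """Normalized, dimensionless reflectance cube ``I(i, j, lambda)``."""

    values: np.ndarray
    wavelengths: np.ndarray
    pixel_pitch: tuple[float, float] = (0.3, 0.3)  # mm/pixel (Y, X)
    working_distance: float = 300.0  # mm, camera to reference plane
    valid_mask: np.ndarray | None = None  # (ni, nj), True where trustworthy
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = _as_float(self.values)
        self.wavelengths = _as_float(self.wavelengths)
        if self.values.ndim != 3:
            raise ValueError("values must be (rows, cols, bands)")
        if self.wavelengths.shape != (self.values.shape[2],):
            raise ValueError("wavelength vector length does not match band axis")
        nl = self.wavelengths.size
        if nl > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape[:2]:
                raise ValueError("valid_mask shape does not match spatial grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ReflectanceCube":
        return replace(
            self,
            values=self.values.copy(),
            valid_mask=self.valid_mask.copy(),
            provenance=dict(self.provenance),
        )


@dataclass
class HeightMap:
    """Surface height in mm on the cube's pixel grid; larger z is closer to the camera."""

    z: np.ndarray
    valid_mask: np.ndarray | None = None
    pixel_pitch: tuple[float, float] = (0.3, 0.3)

    def __post_init__(self):
        self.z = _as_float(self.z)
        if self.z.ndim != 2:
            raise ValueError("height map must be 2-D")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.z)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.z.shape:
                raise ValueError("valid_mask shape does not match height grid")
        if not np.all(np.isfinite(self.z[self.valid_mask])):
            raise ValueError("height values must be finite where valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape


def normalize_reflectance(scan: RawScan) -> ReflectanceCube:
    """Convert raw counts to normalized reflectance ``I = (R - D) / (W - D)``.

    Pixels where the white-minus-dark denominator is not strictly positive at
    every band are flagged invalid rather than clipped; negative reflectance
    from noise below the dark level is likewise kept and left to downstream
    masking, because clipping would bias spectral fits.
    """
    dark = scan.dark3
    denom = scan.white - dark
    bad = ~np.all(denom > 0, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (scan.raw - dark) / denom
    values[bad, :] = np.nan
    return ReflectanceCube(
        values=values,
        wavelengths=scan.wavelengths.copy(),
        pixel_pitch=scan.pixel_pitch,
        working_distance=scan.working_distance,
        valid_mask=~bad,
        provenance={"normalized": True},
    )


def bin_cube(cube: ReflectanceCube, spatial_factor: int = 1, spectral_factor: int = 1) -> ReflectanceCube:
    """Block-mean binning over non-overlapping windows.

    ``spatial_factor`` applies to both spatial axes, ``spectral_factor`` to the
    band axis. Trailing partial blocks are dropped. A binned pixel is valid only
    if every contributing pixel was valid; the mean over a fully tiled region is
    conserved to machine precision.
    """
    fs, fl = int(spatial_factor), int(spectral_factor)
    if fs < 1 or fl < 1:
        raise ValueError("binning factors must be >= 1")
    ni, nj, nl = cube.shape
    if fs > ni or fs > nj or fl > nl:
        raise ValueError("binning factor exceeds axis length")
    mi, mj, ml = ni // fs, nj // fs, nl // fl
    v = cube.values[: mi * fs, : mj * fs, : ml * fl]
    v = v.reshape(mi, fs, mj, fs, ml, fl).mean(axis=(1, 3, 5))
    m = cube.valid_mask[: mi * fs, : mj * fs].reshape(mi, fs, mj, fs).all(axis=(1, 3))
    wl = cube.wavelengths[: ml * fl].reshape(ml, fl).mean(axis=1)
    prov = dict(cube.provenance)
    prov["binned"] = (fs, fl)
    return ReflectanceCube(
        values=v,
        wavelengths=wl,
        pixel_pitch=(cube.pixel_pitch[0] * fs, cube.pixel_pitch[1] * fs),
        working_distance=cube.working_distance,
        valid_mask=m,
        provenance=prov,
    )


def bin_height(h: HeightMap, spatial_factor: int) -> HeightMap:
    """Block-mean a height map with the same convention as :func:`bin_cube`."""
    fs = int(spatial_factor)
    if fs < 1:
        raise ValueError("binning factor must be >= 1")
    ni, nj = h.shape
    if fs > ni or fs > nj:
        raise ValueError("binning factor exceeds axis length")
    mi, mj = ni // fs, nj // fs
    z = h.z[: mi * fs, : mj * fs].reshape(mi, fs, mj, fs)
    m = h.valid_mask[: mi * fs, : mj * fs].reshape(mi, fs, mj, fs)
    with np.errstate(invalid="ignore"):
        zb = np.where(m, z, 0.0).sum(axis=(1, 3)) / np.maximum(m.sum(axis=(1, 3)), 1)
    mb = m.any(axis=(1, 3))
    zb[~mb] = np.nan
    return HeightMap(z=zb, valid_mask=mb, pixel_pitch=(h.pixel_pitch[0] * fs, h.pixel_pitch[1] * fs))
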