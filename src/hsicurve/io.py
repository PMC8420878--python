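"""Readers and writers: ENVI header+binary, multipage TIFF, and an HDF5 layout.

The canonical lossless dialect is HDF5::

    /reflectance      float64 (i, j, lambda)
    /wavelengths_nm   float64 (lambda,)
    /height_mm        float64 (i, j)        [optional]
    /valid_mask       bool    (i, j)        [optional]
    attrs: pixel_pitch_mm (2,), working_distance_mm

ENVI files are a plain-text ``.hdr`` plus a raw binary cube in BSQ, BIL or BIP
interleave; multipage TIFF stores bands as pages with a JSON sidecar carrying
the wavelength vector and grid metadata. Pixel (0, 0) is the first sample of
the first scan line in every dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .datacube import HeightMap, RawScan, ReflectanceCube

__all__ = [
    "read_cube",
    "write_cube",
    "read_height",
    "write_height",
    "write_map",
    "read_map",
    "read_rawscan",
    "write_rawscan",
]

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


# ---------------------------------------------------------------------------
# HDF5


def write_cube_hdf5(path, cube: ReflectanceCube, height: HeightMap | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.values)
        f.create_dataset("wavelengths_nm", data=cube.wavelengths)
        f.create_dataset("valid_mask", data=cube.valid_mask)
        if height is not None:
            f.create_dataset("height_mm", data=height.z)
            f.create_dataset("height_valid", data=height.valid_mask)
        f.attrs["pixel_pitch_mm"] = np.asarray(cube.pixel_pitch, dtype=float)
        f.attrs["working_distance_mm"] = float(cube.working_distance)
        f.attrs["provenance"] = json.dumps(cube.provenance)


def read_cube_hdf5(path) -> ReflectanceCube:
    with h5py.File(path, "r") as f:
        if "wavelengths_nm" not in f:
            raise ValueError("HDF5 cube is missing the wavelength vector")
        cube = ReflectanceCube(
            values=f["reflectance"][()],
            wavelengths=f["wavelengths_nm"][()],
            pixel_pitch=tuple(f.attrs.get("pixel_pitch_mm", (0.3, 0.3))),
            working_distance=float(f.attrs.get("working_distance_mm", 300.0)),
            valid_mask=f["valid_mask"][()] if "valid_mask" in f else None,
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )
    return cube


def read_height_hdf5(path) -> HeightMap:
    with h5py.File(path, "r") as f:
        if "height_mm" not in f:
            raise ValueError("HDF5 file has no /height_mm dataset")
        return HeightMap(
            z=f["height_mm"][()],
            valid_mask=f["height_valid"][()] if "height_valid" in f else None,
            pixel_pitch=tuple(f.attrs.get("pixel_pitch_mm", (0.3, 0.3))),
        )


def write_rawscan(path, scan: RawScan):
    """Store an acquisition (raw + dark + white frames) losslessly in HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=scan.raw)
        f.create_dataset("dark", data=scan.dark)
        f.create_dataset("white", data=scan.white)
        f.create_dataset("wavelengths_nm", data=scan.wavelengths)
        f.attrs["pixel_pitch_mm"] = np.asarray(scan.pixel_pitch, dtype=float)
        f.attrs["working_distance_mm"] = float(scan.working_distance)


def read_rawscan(path) -> RawScan:
    with h5py.File(path, "r") as f:
        if "wavelengths_nm" not in f:
            raise ValueError("raw scan file is missing the wavelength vector")
        return RawScan(
            raw=f["raw"][()],
            dark=f["dark"][()],
            white=f["white"][()],
            wavelengths=f["wavelengths_nm"][()],
            pixel_pitch=tuple(f.attrs.get("pixel_pitch_mm", (0.3, 0.3))),
            working_distance=float(f.attrs.get("working_distance_mm", 300.0)),
        )


# ---------------------------------------------------------------------------
# ENVI


def write_cube_envi(path, cube: ReflectanceCube, interleave: str = "bsq", dtype=np.float64):
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError("interleave must be bsq, bil or bip")
    ni, nj, nl = cube.shape
    v = cube.values.astype(dtype)
    if interleave == "bsq":
        arr = np.transpose(v, (2, 0, 1))  # (bands, lines, samples)
    elif interleave == "bil":
        arr = np.transpose(v, (0, 2, 1))  # (lines, bands, samples)
    else:
        arr = v  # (lines, samples, bands)
    data_file = path.with_suffix(".dat")
    arr.tofile(data_file)
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {nj}\n"
        f"lines = {ni}\n"
        f"bands = {nl}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
        f"pixel size = {{ {cube.pixel_pitch[1]}, {cube.pixel_pitch[0]} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    return data_file


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    in_brace = False
    for line in text.splitlines():
        if in_brace:
            buf += " " + line.strip()
            if "}" in line:
                fields[key] = buf
                in_brace = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            buf = val
            in_brace = True
        else:
            fields[key] = val
    return fields


def read_cube_envi(path) -> ReflectanceCube:
    path = Path(path)
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        nj = int(fields["samples"])
        ni = int(fields["lines"])
        nl = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
        interleave = fields["interleave"].lower()
    except KeyError as e:
        raise ValueError(f"malformed ENVI header: missing {e}") from e
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    wl = np.array([float(t) for t in fields["wavelength"].strip("{} ").split(",") if t.strip()])
    if wl.size != nl:
        raise ValueError("wavelength list length does not match band count")
    data_file = hdr_path.with_suffix(".dat")
    arr = np.fromfile(data_file, dtype=dtype)
    if arr.size != ni * nj * nl:
        raise ValueError("ENVI binary size does not match header dimensions")
    if interleave == "bsq":
        v = np.transpose(arr.reshape(nl, ni, nj), (1, 2, 0))
    elif interleave == "bil":
        v = np.transpose(arr.reshape(ni, nl, nj), (0, 2, 1))
    elif interleave == "bip":
        v = arr.reshape(ni, nj, nl)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    pitch = (0.3, 0.3)
    if "pixel size" in fields:
        px = [float(t) for t in fields["pixel size"].strip("{} ").split(",")]
        pitch = (px[1], px[0])
    return ReflectanceCube(values=v.astype(np.float64), wavelengths=wl, pixel_pitch=pitch)


# ---------------------------------------------------------------------------
# TIFF


def write_cube_tiff(path, cube: ReflectanceCube):
    path = Path(path)
    tifffile.imwrite(path, np.transpose(cube.values, (2, 0, 1)).astype(np.float32))
    sidecar = {
        "wavelengths_nm": cube.wavelengths.tolist(),
        "pixel_pitch_mm": list(cube.pixel_pitch),
        "working_distance_mm": cube.working_distance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_cube_tiff(path) -> ReflectanceCube:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError("TIFF cube requires a JSON sidecar with the wavelength vector")
    sidecar = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    return ReflectanceCube(
        values=np.transpose(pages, (1, 2, 0)).astype(np.float64),
        wavelengths=np.asarray(sidecar["wavelengths_nm"]),
        pixel_pitch=tuple(sidecar.get("pixel_pitch_mm", (0.3, 0.3))),
        working_distance=sidecar.get("working_distance_mm", 300.0),
    )


# ---------------------------------------------------------------------------
# dispatch


def _dialect_of(path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".hdr", ".dat"):
        return "envi"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer dialect from {path}")


def read_cube(path, dialect: str | None = None) -> ReflectanceCube:
    d = _dialect_of(path, dialect)
    return {"hdf5": read_cube_hdf5, "envi": read_cube_envi, "tiff": read_cube_tiff}[d](path)


def write_cube(path, cube: ReflectanceCube, dialect: str | None = None, **kw):
    d = _dialect_of(path, dialect)
    return {"hdf5": write_cube_hdf5, "envi": write_cube_envi, "tiff": write_cube_tiff}[d](path, cube, **kw)


def read_height(path) -> HeightMap:
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return read_height_hdf5(path)
    if suffix in (".tif", ".tiff"):
        z = tifffile.imread(path).astype(np.float64)
        return HeightMap(z=z)
    raise ValueError(f"unsupported height format {suffix}")


def write_height(path, h: HeightMap):
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("height_mm", data=h.z)
            f.create_dataset("height_valid", data=h.valid_mask)
            f.attrs["pixel_pitch_mm"] = np.asarray(h.pixel_pitch, dtype=float)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, h.z.astype(np.float32))
    else:
        raise ValueError(f"unsupported height format {suffix}")


def write_map(path, arrays: dict[str, np.ndarray], attrs: dict | None = None):
    """Store named per-pixel parameter grids (fit output) in HDF5."""
    with h5py.File(path, "w") as f:
        for k, v in arrays.items():
            f.create_dataset(k, data=np.asarray(v))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def read_map(path) -> tuple[dict[str, np.ndarray], dict]:
    arrays, attrs = {}, {}
    with h5py.File(path, "r") as f:

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                arrays[name] = obj[()]

        f.visititems(visit)
        for k in f.attrs:
            attrs[k] = f.attrs[k]
    return arrays, attrs
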