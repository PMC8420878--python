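"""Tissue and phantom optical-property models.

Two sample models feed the radiative-transfer solver:

* a one-layer silicone (SiliGlass) phantom whose absorption comes from a
  pre-diluted pigment mixed into the medium and whose scattering comes from
  polydisperse silica microspheres (Lorenz-Mie), and
* a two-layer skin model: a thin melanin-bearing epidermis over a thick dermis
  absorbing through deoxy/oxyhemoglobin, bilirubin and cytochrome c oxidase,
  with a power-law reduced-scattering ansatz shared by both layers.

Concentration conventions mirror the mixed units of the underlying models:
melanin and hemoglobins are volume fractions given in percent, bilirubin and
cytochromes are millimolar concentrations against per-mM extinction curves.
Bundled extinction tables are synthetic compilations (see ``data/``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomParams",
    "SkinParams",
    "LayerOpticalProperties",
    "SphereDistribution",
    "ExtinctionTables",
    "phantom_masses",
    "siliglass_refractive_index",
    "phantom_mua",
    "distribution_scattering",
    "epidermis_mua",
    "dermis_mua",
    "skin_mus_prime",
    "skin_refractive_index",
    "build_slab",
    "default_wavelength_grid",
    "PHANTOM_CONFIG",
    "SKIN_G",
    "SKIN_B",
    "SKIN_BASELINE_MUA",
    "EPIDERMIS_THICKNESS_CM",
    "DERMIS_THICKNESS_CM",
]

_DATA = resources.files("hsicurve") / "data"

PHANTOM_CONFIG: dict = json.loads((_DATA / "phantom_config.json").read_text())

SKIN_G = 0.82  # scattering anisotropy of both skin layers
SKIN_B = 1.27  # scattering power, fixed
SKIN_BASELINE_MUA = 0.25  # cm^-1, baseline absorption of bloodless skin
EPIDERMIS_THICKNESS_CM = 0.01  # 100 um
DERMIS_THICKNESS_CM = 1.0


def default_wavelength_grid(start: float = 430.0, stop: float = 700.0, step: float = 5.0) -> np.ndarray:
    """The fitting grid: 430-700 nm in 5-nm steps by default."""
    return np.arange(start, stop + step / 2, step)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class PhantomParams:
    """Free parameters of the one-layer phantom model, in percent."""

    Cabs: float  # diluted-absorber volume fraction, %
    Csc: float  # scatterer volume fraction, %

    BOUNDS = {"Cabs": (0.1, 45.0), "Csc": (0.1, 10.0)}
    FREE = ("Cabs", "Csc")

    def __post_init__(self):
        if not (0.0 <= self.Cabs <= 100.0 and 0.0 <= self.Csc <= 100.0):
            raise ValueError("volume fractions must lie in [0, 100] percent")

    def free_values(self) -> np.ndarray:
        return np.array([self.Cabs, self.Csc], dtype=float)

    @classmethod
    def from_free_values(cls, v) -> "PhantomParams":
        return cls(Cabs=float(v[0]), Csc=float(v[1]))


@dataclass
class SkinParams:
    """Two-layer skin model parameters.

    ``fmel``, ``fHb``, ``fHbO2`` are volume fractions in percent; ``fCytO``,
    ``fCytOO2`` millimolar; ``a`` the reduced scattering at 500 nm in cm^-1.
    ``fbil`` (mM) is not a free parameter and defaults to zero. ``b``, layer
    thicknesses and ``g`` are fixed model constants.
    """

    fmel: float = 1.5
    fHb: float = 0.5
    fHbO2: float = 1.0
    fCytO: float = 0.3
    fCytOO2: float = 0.3
    a: float = 35.0
    fbil: float = 0.0

    BOUNDS = {
        "fmel": (0.1, 15.0),
        "fHb": (0.1, 20.0),
        "fHbO2": (0.1, 20.0),
        "fCytO": (0.1, 2.0),
        "fCytOO2": (0.1, 2.0),
        "a": (20.0, 50.0),
    }
    FREE = ("fmel", "fHb", "fHbO2", "fCytO", "fCytOO2", "a")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.FREE], dtype=float)

    @classmethod
    def from_free_values(cls, v, fbil: float = 0.0) -> "SkinParams":
        return cls(**{k: float(x) for k, x in zip(cls.FREE, v)}, fbil=fbil)

    @property
    def blood_fraction(self) -> float:
        return self.fHb + self.fHbO2

    @property
    def oxygen_saturation(self) -> float:
        tot = self.blood_fraction
        return self.fHbO2 / tot if tot > 0 else np.nan


@dataclass
class LayerOpticalProperties:
    """Per-layer optical properties consumed by the slab solver.

    ``mua``/``mus`` in cm^-1 (scalar or per-wavelength), anisotropy ``g``,
    refractive index ``n``, and geometric thickness in cm.
    """

    mua: np.ndarray | float
    mus: np.ndarray | float
    g: np.ndarray | float
    n: np.ndarray | float
    thickness: float

    def __post_init__(self):
        if np.any(np.asarray(self.mua) < 0) or np.any(np.asarray(self.mus) < 0):
            raise ValueError("mua and mus must be non-negative")
        gv = np.asarray(self.g)
        if np.any(gv < 0) or np.any(gv >= 1):
            raise ValueError("anisotropy must satisfy 0 <= g < 1")
        if np.any(np.asarray(self.n) < 1):
            raise ValueError("refractive index must be >= 1")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class SphereDistribution:
    """Discrete volume-fraction distribution of microsphere radii (um)."""

    radii: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.radii.size == 0:
            raise ValueError("empty distribution")
        if np.any(self.radii <= 0) or np.any(self.volume_fraction < 0):
            raise ValueError("radii must be positive, fractions non-negative")

    _default = None  # class-level cache of the bundled table

    @classmethod
    def load_default(cls) -> "SphereDistribution":
        if cls._default is None:
            arr = np.loadtxt(_DATA / "synthetic_spheres.csv", delimiter=",", skiprows=1)
            cls._default = cls(radii=arr[:, 0], volume_fraction=arr[:, 1])
        return cls._default


@dataclass
class ExtinctionTables:
    """Tabulated extinction/absorption curves on a common wavelength grid."""

    wavelengths: np.ndarray
    curves: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    KEYS = ("Hb", "HbO2", "bil", "CytO", "CytOO2", "AB", "abs")

    def __call__(self, key: str, grid: np.ndarray) -> np.ndarray:
        """Curve resampled to ``grid`` by linear interpolation."""
        grid = np.asarray(grid, dtype=float)
        if grid.min() < self.wavelengths.min() - 1e-9 or grid.max() > self.wavelengths.max() + 1e-9:
            raise ValueError(
                f"grid [{grid.min()}, {grid.max()}] nm outside table coverage "
                f"[{self.wavelengths.min()}, {self.wavelengths.max()}] nm"
            )
        return np.interp(grid, self.wavelengths, self.curves[key])

    @classmethod
    def load_default(cls) -> "ExtinctionTables":
        def read(name):
            path = _DATA / name
            with resources.as_file(path) as p:
                header = Path(p).read_text().splitlines()[0].split(",")
                arr = np.loadtxt(p, delimiter=",", skiprows=1)
            return header, arr

        curves = {}
        h, a = read("synthetic_hemoglobin.csv")
        lam = a[:, 0]
        curves["Hb"], curves["HbO2"] = a[:, 1], a[:, 2]
        _, a = read("synthetic_bilirubin.csv")
        curves["bil"] = a[:, 1]
        _, a = read("synthetic_cytochrome.csv")
        curves["CytO"], curves["CytOO2"] = a[:, 1], a[:, 2]
        _, a = read("synthetic_siliglass.csv")
        curves["AB"], curves["abs"] = a[:, 1], a[:, 2]
        meta = {
            "provenance": PHANTOM_CONFIG.get("provenance", "synthetic"),
            "units": {
                "Hb": "cm^-1 at whole-blood volume fraction 1",
                "HbO2": "cm^-1 at whole-blood volume fraction 1",
                "bil": "cm^-1 per mM",
                "CytO": "cm^-1 per mM (reduced)",
                "CytOO2": "cm^-1 per mM (oxidized)",
                "AB": "cm^-1, clear polymerized medium",
                "abs": "cm^-1, pigment at 5.83e-5 mass fraction",
            },
        }
        return cls(wavelengths=lam, curves=curves, meta=meta)


_DEFAULT_TABLES: ExtinctionTables | None = None


def default_tables() -> ExtinctionTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = ExtinctionTables.load_default()
    return _DEFAULT_TABLES


# ---------------------------------------------------------------------------
# phantom model


def phantom_masses(Cabs: float, Csc: float, mA: float, wall_loss: bool = False) -> tuple[float, float, float]:
    """Ingredient masses (g) for target fractional concentrations.

    ``Cabs`` and ``Csc`` are *fractional* (e.g. 0.037 for 3.7%). Returns
    ``(mabs, msc, mB)`` for a given mass of part A. With ``wall_loss`` the
    empirical +1 g cup-wall adjustment is applied to part B (and the scatterer
    mass rescaled to keep the target concentration).
    """
    if not 0.0 <= Cabs < 0.5:
        raise ValueError("Cabs (fractional) must lie in [0, 0.5): pole at 1/2")
    if Csc < 0 or mA <= 0:
        raise ValueError("Csc must be >= 0 and mA > 0")
    mabs = 2.0 * Cabs * mA / (1.0 - 2.0 * Cabs)
    msc = 2.0 * Csc * (mA + mabs)
    mB = mA + mabs - msc
    if wall_loss:
        extra = float(PHANTOM_CONFIG.get("wall_loss_g", 1.0))
        mB += extra
        # keep Csc = msc / (total) after the wall-loss addition
        msc = 2.0 * Csc * (mA + mabs + extra / 2.0)
    return mabs, msc, mB


def siliglass_refractive_index(lam_nm) -> np.ndarray:
    """Sellmeier-form refractive index of the polymerized phantom medium."""
    lam = np.asarray(lam_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    lr2 = (lam / 436.4) ** 2
    denom = lr2 - 0.05943376
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("wavelength at the Sellmeier pole")
    return np.sqrt(1.0 + 0.95007197 * lr2 / denom)


def phantom_mua(params: PhantomParams, tables: ExtinctionTables | None, grid) -> np.ndarray:
    """Phantom absorption: medium plus diluted pigment.

    ``mua = CAB * mu_AB + Cabs * mu_abs / 0.13246`` with ``CAB = 1 - Cabs``
    (volume fractions). The constant rescales the pigment curve, which was
    measured at a different dilution than the one used in the recipe.
    """
    if tables is None:
        tables = default_tables()
    grid = np.asarray(grid, dtype=float)
    cabs = params.Cabs / 100.0
    cab = 1.0 - cabs
    if PHANTOM_CONFIG.get("cab_subtract_scatterer", False):
        cab = cab - params.Csc / 100.0
    denom = float(PHANTOM_CONFIG["dilution_denominator"])
    return cab * tables("AB", grid) + cabs * tables("abs", grid) / denom


_MIE_CACHE: dict = {}


def distribution_scattering(
    dist: SphereDistribution,
    Csc: float,
    grid,
    n_sphere: float | None = None,
    n_medium=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Polydisperse Mie scattering of the microsphere suspension.

    Per radius bin ``mus_i = 3 phi_i Qsca_i / (4 r_i)`` (volume-fraction form);
    ``mus = Csc * sum_i mus_i`` with fractional ``Csc``, and the anisotropy is
    the scattering-weighted mean of the single-sphere values. Returns
    ``(mus, g)`` per wavelength.
    """
    from .mie import mie_efficiencies  # local import keeps module load cheap

    grid = np.asarray(grid, dtype=float)
    if n_sphere is None:
        n_sphere = float(PHANTOM_CONFIG["sphere_index"])
    if n_medium is None:
        n_medium = siliglass_refractive_index(grid)
    n_medium = np.broadcast_to(np.asarray(n_medium, dtype=float), grid.shape)

    key = (dist.radii.tobytes(), dist.volume_fraction.tobytes(), n_sphere, grid.tobytes(), n_medium.tobytes())
    if key in _MIE_CACHE:
        mus_cal, g = _MIE_CACHE[key]
    else:
        phi = dist.volume_fraction
        radii_cm = dist.radii * 1e-4
        mus_cal = np.zeros(grid.size)
        musg = np.zeros(grid.size)
        for l, (lam, nm) in enumerate(zip(grid, n_medium)):
            x = 2.0 * np.pi * dist.radii * nm / (lam * 1e-3)
            tot = 0.0
            totg = 0.0
            for ri, xi, pi in zip(radii_cm, x, phi):
                if pi == 0.0:
                    continue
                _, qs, gi = mie_efficiencies(n_sphere / nm, xi)
                mi = 3.0 * pi * qs / (4.0 * ri)
                tot += mi
                totg += mi * gi
            mus_cal[l] = tot
            musg[l] = totg
        g = np.where(mus_cal > 0, musg / np.maximum(mus_cal, 1e-300), 0.0)
        _MIE_CACHE[key] = (mus_cal, g)
    return Csc * mus_cal, g


# ---------------------------------------------------------------------------
# skin model


def melanin_mua(grid) -> np.ndarray:
    """Melanosome absorption power law, cm^-1 at volume fraction 1."""
    lam = np.asarray(grid, dtype=float)
    return 6.6e11 * lam ** (-3.33)


def epidermis_mua(fmel_percent: float, grid) -> np.ndarray:
    """Epidermal absorption: melanin power law plus the bloodless-skin baseline."""
    if fmel_percent < 0:
        raise ValueError("melanin fraction must be >= 0")
    return (fmel_percent / 100.0) * melanin_mua(grid) + SKIN_BASELINE_MUA


def dermis_mua(params: SkinParams, tables: ExtinctionTables | None, grid) -> np.ndarray:
    """Dermal absorption: hemoglobins, bilirubin, cytochromes, baseline."""
    if tables is None:
        tables = default_tables()
    grid = np.asarray(grid, dtype=float)
    return (
        (params.fHb / 100.0) * tables("Hb", grid)
        + (params.fHbO2 / 100.0) * tables("HbO2", grid)
        + params.fbil * tables("bil", grid)
        + params.fCytO * tables("CytO", grid)
        + params.fCytOO2 * tables("CytOO2", grid)
        + SKIN_BASELINE_MUA
    )


def skin_mus_prime(a: float, b: float, grid) -> np.ndarray:
    """Reduced scattering power-law ansatz, pivoted at 500 nm."""
    if a <= 0:
        raise ValueError("a must be positive")
    lam = np.asarray(grid, dtype=float)
    return a * (lam / 500.0) ** (-b)


def skin_refractive_index(grid) -> np.ndarray:
    """Cauchy-type dispersion of skin, common to epidermis and dermis."""
    lam = np.asarray(grid, dtype=float)
    return 1.309 + 4.36e2 * lam**-2 + 1.6065e9 * lam**-4 - 1.12811e14 * lam**-6


# ---------------------------------------------------------------------------
# slab assembly


def build_slab(
    model: str,
    params: PhantomParams | SkinParams,
    grid=None,
    tables: ExtinctionTables | None = None,
    dist: SphereDistribution | None = None,
) -> list[LayerOpticalProperties]:
    """Build the ordered layer stack for one of the two sample models.

    ``model='phantom'``: one 2-cm layer with Sellmeier index and Mie-derived
    scattering. ``model='skin'``: 100-um epidermis over 1-cm dermis, both with
    the skin dispersion, ``g = 0.82`` and the shared reduced-scattering ansatz.
    """
    if grid is None:
        grid = default_wavelength_grid()
    grid = np.asarray(grid, dtype=float)
    if model == "phantom":
        if not isinstance(params, PhantomParams):
            raise TypeError("phantom model needs PhantomParams")
        if dist is None:
            dist = SphereDistribution.load_default()
        mua = phantom_mua(params, tables, grid)
        mus, g = distribution_scattering(dist, params.Csc / 100.0, grid)
        n = siliglass_refractive_index(grid)
        return [
            LayerOpticalProperties(
                mua=mua, mus=mus, g=g, n=n,
                thickness=float(PHANTOM_CONFIG.get("thickness_cm", 2.0)),
            )
        ]
    if model == "skin":
        if not isinstance(params, SkinParams):
            raise TypeError("skin model needs SkinParams")
        n = skin_refractive_index(grid)
        musp = skin_mus_prime(params.a, SKIN_B, grid)
        mus = musp / (1.0 - SKIN_G)
        epi = LayerOpticalProperties(
            mua=epidermis_mua(params.fmel, grid), mus=mus, g=SKIN_G, n=n,
            thickness=EPIDERMIS_THICKNESS_CM,
        )
        derm = LayerOpticalProperties(
            mua=dermis_mua(params, tables, grid), mus=mus, g=SKIN_G, n=n,
            thickness=DERMIS_THICKNESS_CM,
        )
        return [epi, derm]
    raise ValueError(f"unknown model {model!r}")
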