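"""Per-pixel inversion of reflectance spectra to model parameters.

Each pixel spectrum is matched to the adding-doubling forward model of the
chosen sample (one-layer phantom or two-layer skin) by bounded nonlinear least
squares: Levenberg-Marquardt in a logistic transform of the box-constrained
parameters, so the optimizer stays smooth while fits driven toward a bound are
still detectable (``at_bound`` flags). Initialization follows the multi-start
recipe: the mean spectrum of a small reference region is fitted from many
random starting points inside the bounds and the best-R^2 parameters seed
every pixel fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .adddoubling import QuadratureScheme, add_boundaries_and_layers, hg_redistribution
from .datacube import ReflectanceCube, bin_cube
from .optics import PhantomParams, SkinParams, build_slab, default_wavelength_grid

__all__ = [
    "FitConfig",
    "FitResult",
    "ParameterMap",
    "ForwardModel",
    "fit_spectrum",
    "multistart_init",
    "fit_cube",
    "radial_average",
    "max_valid_angle",
]


@dataclass
class FitConfig:
    """Knobs of the inversion: model, bounds, grid, initialization, seeds."""

    model: str = "phantom"  # 'phantom' | 'skin'
    bounds: dict[str, tuple[float, float]] | None = None  # default: model bounds
    lambda_start: float = 430.0
    lambda_stop: float = 700.0
    lambda_step: float = 5.0
    max_iterations: int = 200
    n_starts: int = 1000
    seed: int = 0
    batch_size: int = 500
    spatial_binning: int = 8
    spectral_binning: int = 6
    init_region: tuple[int, int] | None = None  # top-left corner of the 10x10 region
    init_region_size: int = 10
    fbil: float = 0.0  # mM, fixed (not a free parameter)

    def params_class(self):
        return {"phantom": PhantomParams, "skin": SkinParams}[self.model]

    def get_bounds(self) -> dict[str, tuple[float, float]]:
        return dict(self.bounds or self.params_class().BOUNDS)

    def grid(self) -> np.ndarray:
        return default_wavelength_grid(self.lambda_start, self.lambda_stop, self.lambda_step)


@dataclass
class FitResult:
    params: np.ndarray  # free parameter values, model order
    names: tuple[str, ...]
    r_squared: float
    converged: bool
    n_iter: int
    at_bound: np.ndarray  # bool per free parameter

    def as_params(self, cfg: FitConfig):
        cls = cfg.params_class()
        if cls is SkinParams:
            return SkinParams.from_free_values(self.params, fbil=cfg.fbil)
        return cls.from_free_values(self.params)


@dataclass
class ParameterMap:
    """Per-pixel fitted parameter grids plus goodness of fit and validity."""

    params: dict[str, np.ndarray]
    r_squared: np.ndarray
    valid: np.ndarray
    at_bound: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.r_squared.shape


class ForwardModel:
    """Reflectance-spectrum evaluator with precomputed wavelength-fixed pieces.

    The quadrature scheme, the Henyey-Greenstein redistribution matrices and
    (for the phantom) the Mie scattering curves depend only on the model and
    grid, not on the fitted concentrations, so they are built once.
    """

    def __init__(self, model: str, grid: np.ndarray, cfg: FitConfig | None = None, M: int = 20):
        self.model = model
        self.grid = np.asarray(grid, dtype=float)
        self.cfg = cfg or FitConfig(model=model)
        ref = self._slab(self._reference_params())
        self.scheme = QuadratureScheme.for_slab(ref, 1.0, M)
        self.hg = [
            hg_redistribution(np.atleast_1d(np.asarray(l.g, dtype=float)), self.scheme)
            for l in ref
        ]

    def _reference_params(self):
        return PhantomParams(10.0, 3.0) if self.model == "phantom" else SkinParams()

    def _slab(self, p):
        return build_slab(self.model, p, self.grid)

    def params_from_values(self, values):
        if self.model == "skin":
            return SkinParams.from_free_values(values, fbil=self.cfg.fbil)
        return PhantomParams.from_free_values(values)

    def reflectance(self, values) -> np.ndarray:
        """R(lambda) for a vector of free parameter values."""
        slab = self._slab(self.params_from_values(values))
        res = add_boundaries_and_layers(slab, 1.0, self.scheme, hg_per_layer=self.hg)
        return res.R_total


# ---------------------------------------------------------------------------
# bounded LM via logistic transform


def _to_internal(p, lo, hi):
    q = np.clip((p - lo) / (hi - lo), 1e-6, 1 - 1e-6)
    return np.log(q / (1 - q))


def _from_internal(u, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-np.clip(u, -50.0, 50.0)))


def _r_squared(measured, modeled):
    ss_res = float(np.sum((measured - modeled) ** 2))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)


def fit_spectrum(
    measured: np.ndarray,
    model: ForwardModel | str,
    cfg: FitConfig | None = None,
    init: np.ndarray | None = None,
    measured_wavelengths: np.ndarray | None = None,
) -> FitResult:
    """Fit one reflectance spectrum; returns parameters, R^2 and diagnostics.

    ``measured`` is resampled onto the model grid first when its own
    wavelength axis is supplied. Non-finite residuals mark the fit failed
    instead of raising.
    """
    cfg = cfg or FitConfig(model=model if isinstance(model, str) else model.model)
    fm = ForwardModel(cfg.model, cfg.grid(), cfg) if isinstance(model, str) else model
    measured = np.asarray(measured, dtype=float)
    if measured_wavelengths is not None:
        measured = np.interp(fm.grid, np.asarray(measured_wavelengths, float), measured)
    if measured.shape != fm.grid.shape:
        raise ValueError("measured spectrum does not match the fitting grid")
    bounds = cfg.get_bounds()
    names = tuple(cfg.params_class().FREE)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    if init is None:
        init = 0.5 * (lo + hi)
    init = np.clip(np.asarray(init, dtype=float), lo, hi)

    bad = {"flag": False}

    def resid(u):
        r = fm.reflectance(_from_internal(u, lo, hi)) - measured
        if not np.all(np.isfinite(r)):
            bad["flag"] = True
            return np.full_like(measured, 1e3)
        return r

    if not np.all(np.isfinite(measured)):
        return FitResult(
            params=np.full(lo.size, np.nan), names=names, r_squared=-np.inf,
            converged=False, n_iter=0, at_bound=np.zeros(lo.size, bool),
        )
    sol = least_squares(
        resid,
        _to_internal(init, lo, hi),
        method="lm",
        max_nfev=cfg.max_iterations * (lo.size + 1),
        xtol=1e-8,
        ftol=1e-8,
    )
    p = _from_internal(sol.x, lo, hi)
    modeled = fm.reflectance(p)
    span = hi - lo
    at_bound = (p - lo < 1e-3 * span) | (hi - p < 1e-3 * span)
    return FitResult(
        params=p,
        names=names,
        r_squared=_r_squared(measured, modeled),
        converged=bool(sol.success) and not bad["flag"],
        n_iter=int(sol.nfev),
        at_bound=at_bound,
    )


def multistart_init(
    region_spectra: np.ndarray,
    model: ForwardModel | str,
    cfg: FitConfig | None = None,
    measured_wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Global initialization from the mean spectrum of a reference region.

    ``region_spectra``: (..., n_lambda); the mean over leading axes is fitted
    from ``cfg.n_starts`` uniform random draws inside the bounds (seeded) and
    the parameters of the highest-R^2 fit are returned. To keep the start
    count affordable on one CPU, every draw is first screened by its residual
    against the target spectrum and only the most promising candidates get a
    full Levenberg-Marquardt refinement.
    """
    cfg = cfg or FitConfig(model=model if isinstance(model, str) else model.model)
    fm = ForwardModel(cfg.model, cfg.grid(), cfg) if isinstance(model, str) else model
    spectra = np.asarray(region_spectra, dtype=float)
    mean_spec = spectra.reshape(-1, spectra.shape[-1])
    mean_spec = mean_spec[np.all(np.isfinite(mean_spec), axis=1)]
    if mean_spec.size == 0:
        raise ValueError("no valid spectra in the initialization region")
    mean_spec = mean_spec.mean(axis=0)
    if measured_wavelengths is not None:
        mean_spec = np.interp(fm.grid, np.asarray(measured_wavelengths, float), mean_spec)
    bounds = cfg.get_bounds()
    names = tuple(cfg.params_class().FREE)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    rng = np.random.default_rng(cfg.seed)
    draws = lo + (hi - lo) * rng.random((max(cfg.n_starts, 1), lo.size))
    # screen all draws by forward residual, refine the best few
    sse = np.empty(draws.shape[0])
    for i, d in enumerate(draws):
        sse[i] = float(np.sum((fm.reflectance(d) - mean_spec) ** 2))
    n_refine = min(8, draws.shape[0])
    best_r2 = -np.inf
    best = draws[int(np.argmin(sse))]
    for i in np.argsort(sse)[:n_refine]:
        fr = fit_spectrum(mean_spec, fm, cfg, init=draws[i])
        if fr.r_squared > best_r2:
            best_r2 = fr.r_squared
            best = fr.params
    if not np.isfinite(best_r2):
        raise ValueError("all multistart fits failed")
    return best


def fit_cube(
    cube: ReflectanceCube,
    model: str | ForwardModel,
    cfg: FitConfig | None = None,
    bin_first: bool = True,
    init: np.ndarray | None = None,
) -> ParameterMap:
    """Fit every valid pixel of a (binned) cube; returns per-parameter maps.

    The cube is block-binned (default 8 spatial / 6 spectral), resampled to
    the fitting grid, seeded by :func:`multistart_init` on the configured
    reference region, then fitted pixel-by-pixel with the previous pixel's
    solution as a warm start (falling back to the global initialization).
    """
    cfg = cfg or FitConfig(model=model if isinstance(model, str) else model.model)
    if bin_first and (cfg.spatial_binning > 1 or cfg.spectral_binning > 1):
        fs = min(cfg.spatial_binning, *cube.shape[:2])
        fl = min(cfg.spectral_binning, cube.shape[2])
        cube = bin_cube(cube, fs, fl)
    fm = ForwardModel(cfg.model, cfg.grid(), cfg) if isinstance(model, str) else model
    ni, nj, _ = cube.shape
    values = np.empty((ni, nj, cube.wavelengths.size))
    values[:] = cube.values
    # resample onto the fitting grid
    spectra = np.empty((ni, nj, fm.grid.size))
    for b, lam in enumerate(fm.grid):
        spectra[:, :, b] = _interp_band(cube.wavelengths, values, lam)

    if init is None:
        r0, c0 = cfg.init_region or (
            max(ni // 2 - cfg.init_region_size // 2, 0),
            max(nj // 2 - cfg.init_region_size // 2, 0),
        )
        size = cfg.init_region_size
        region = spectra[r0 : r0 + size, c0 : c0 + size][
            cube.valid_mask[r0 : r0 + size, c0 : c0 + size]
        ]
        init = multistart_init(region, fm, cfg)

    names = tuple(cfg.params_class().FREE)
    out = {k: np.full((ni, nj), np.nan) for k in names}
    at_bound = {k: np.zeros((ni, nj), bool) for k in names}
    r2 = np.full((ni, nj), np.nan)
    ok = np.zeros((ni, nj), bool)
    n_fail = 0
    for i in range(ni):
        warm = None
        for j in range(nj):
            if not cube.valid_mask[i, j] or not np.all(np.isfinite(spectra[i, j])):
                continue
            fr = fit_spectrum(spectra[i, j], fm, cfg, init=warm if warm is not None else init)
            if not np.all(np.isfinite(fr.params)):
                n_fail += 1
                continue
            for k_idx, k in enumerate(names):
                out[k][i, j] = fr.params[k_idx]
                at_bound[k][i, j] = fr.at_bound[k_idx]
            r2[i, j] = fr.r_squared
            ok[i, j] = True
            warm = fr.params
    meta = {
        "model": cfg.model,
        "seed": cfg.seed,
        "init": np.asarray(init).tolist(),
        "n_failed": n_fail,
        "provenance": dict(cube.provenance),
        "pixel_pitch": cube.pixel_pitch,
    }
    return ParameterMap(params=out, r_squared=r2, valid=ok, at_bound=at_bound, meta=meta)


def _interp_band(wl, values, lam):
    j = np.searchsorted(wl, lam)
    if j == 0:
        return values[:, :, 0]
    if j >= wl.size:
        return values[:, :, -1]
    t = (lam - wl[j - 1]) / (wl[j] - wl[j - 1])
    return (1 - t) * values[:, :, j - 1] + t * values[:, :, j]


# ---------------------------------------------------------------------------
# map metrics


def radial_average(
    values: np.ndarray,
    center: tuple[float, float],
    n_bins: int = 20,
    r_max: float | None = None,
    valid: np.ndarray | None = None,
):
    """Mean and SD of a 2-D field over radial annuli around ``center`` (pixels).

    Returns ``(r_centers, mean, sd, count)``; empty annuli give NaN.
    """
    values = np.asarray(values, dtype=float)
    ni, nj = values.shape
    ii, jj = np.mgrid[0:ni, 0:nj]
    r = np.hypot(ii - center[0], jj - center[1])
    if r_max is None:
        r_max = float(r.max())
    edges = np.linspace(0.0, r_max, n_bins + 1)
    good = np.isfinite(values)
    if valid is not None:
        good &= valid
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    which = np.digitize(r, edges) - 1
    for k in range(n_bins):
        sel = good & (which == k)
        count[k] = int(sel.sum())
        if count[k]:
            mean[k] = values[sel].mean()
            sd[k] = values[sel].std()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, mean, sd, count


def max_valid_angle(
    values: np.ndarray,
    theta: np.ndarray,
    center: tuple[float, float],
    central_value: float | None = None,
    tol: float = 0.05,
    n_bins: int = 20,
    valid: np.ndarray | None = None,
) -> float:
    """Largest inclination angle (deg) within which the map stays near its center.

    Radial annuli are formed around ``center``; the reference is the mean of
    the innermost annuli (the flat central region) unless given. The result is
    the largest mean annulus inclination ``theta_k`` such that every annulus
    up to ``k`` deviates from the reference by at most ``tol`` (relative).
    Returns 0 when already the first annulus deviates.
    """
    _, mean_v, _, cnt_v = radial_average(values, center, n_bins, valid=valid)
    _, mean_t, _, _ = radial_average(np.asarray(theta, dtype=float), center, n_bins, valid=valid)
    present = cnt_v > 0
    if central_value is None:
        inner = np.nonzero(present)[0][:2]
        if inner.size == 0:
            return 0.0
        central_value = float(np.nanmean(mean_v[inner]))
    if central_value == 0:
        return 0.0
    angle = 0.0
    for k in range(n_bins):
        if not present[k]:
            continue
        if abs(mean_v[k] - central_value) / abs(central_value) <= tol:
            angle = max(angle, float(mean_t[k]))
        else:
            break
    return angle
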