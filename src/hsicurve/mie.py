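"""Lorenz-Mie scattering for homogeneous and coated spheres.

Used to derive the scattering coefficient and anisotropy of the silica
microsphere scatterer suspended in the silicone phantom medium. The series is
the canonical one: logarithmic-derivative downward recurrence for the internal
field, Riccati-Bessel upward recurrence for the external field, truncated at
the Wiscombe criterion ``nstop = x + 4 x^{1/3} + 2``.

All sizes are given through the size parameter ``x = 2 pi r n_medium / lambda``
and the relative refractive index ``m = n_sphere / n_medium``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mie_coefficients", "mie_efficiencies", "mie_amplitudes", "mie_sphere", "coated_sphere_efficiencies"]


def _nstop(x: float) -> int:
    n = int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))
    return max(n, 3)


def mie_coefficients(m: complex, x: float) -> tuple[np.ndarray, np.ndarray]:
    """Return the Mie coefficients ``a_n, b_n`` for n = 1..nstop."""
    if x <= 0:
        raise ValueError("size parameter must be positive")
    m = complex(m)
    nmax = _nstop(x)
    # logarithmic derivative D_n(mx) by downward recurrence
    nmx = int(max(nmax, abs(m * x)) + 16)
    D = np.zeros(nmx + 1, dtype=complex)
    mx = m * x
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    # Riccati-Bessel psi, chi of real argument x by upward recurrence
    psi0, psi1 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi0, chi1 = -np.sin(x), np.cos(x)
    a = np.zeros(nmax, dtype=complex)
    b = np.zeros(nmax, dtype=complex)
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi1 - psi0
        chi = (2 * n - 1) / x * chi1 - chi0
        xi = psi - 1j * chi
        xi1 = psi1 - 1j * chi1
        dn = D[n]
        ta = dn / m + n / x
        tb = dn * m + n / x
        a[n - 1] = (ta * psi - psi1) / (ta * xi - xi1)
        b[n - 1] = (tb * psi - psi1) / (tb * xi - xi1)
        psi0, psi1 = psi1, psi
        chi0, chi1 = chi1, chi
    return a, b


def mie_efficiencies(m: complex, x: float) -> tuple[float, float, float]:
    """Return ``(Qext, Qsca, g)`` for a homogeneous sphere."""
    a, b = mie_coefficients(m, x)
    n = np.arange(1, a.size + 1, dtype=float)
    qext = (2.0 / x**2) * np.sum((2 * n + 1) * (a.real + b.real))
    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    # asymmetry parameter
    asy = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    )
    asy += np.sum((2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real)
    g = (4.0 / (x**2 * qsca)) * asy if qsca > 0 else 0.0
    return float(qext), float(qsca), float(g)


def mie_amplitudes(m: complex, x: float, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scattering amplitude functions ``S1(mu), S2(mu)`` at scattering-angle cosines mu.

    Provided chiefly so the efficiency sums can be cross-checked against a
    direct angular integration of the scattered intensity.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    a, b = mie_coefficients(m, x)
    nmax = a.size
    S1 = np.zeros(mu.shape, dtype=complex)
    S2 = np.zeros(mu.shape, dtype=complex)
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)  # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        S1 += f * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        S2 += f * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_np1 = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_np1
    return S1, S2


def _psi_chi(z: float, nmax: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Riccati-Bessel psi_n, chi_n and derivatives for n = 0..nmax (real z)."""
    n_idx = np.arange(0, nmax + 1)
    psi = np.zeros(nmax + 1)
    chi = np.zeros(nmax + 1)
    # psi upward is unstable for n >> z; use downward recurrence for psi
    nstart = nmax + int(np.sqrt(40 * nmax)) + 20
    p_hi, p_lo = 0.0, 1e-30
    psi_d = np.zeros(nmax + 2)
    for n in range(nstart, -1, -1):
        p = (2 * n + 3) / z * p_lo - p_hi
        if n <= nmax:
            psi_d[n] = p
        p_hi, p_lo = p_lo, p
        if abs(p_lo) > 1e250:
            p_hi *= 1e-250
            p_lo *= 1e-250
            psi_d *= 1e-250
    psi = psi_d[: nmax + 1] * (np.sin(z) / psi_d[0])
    chi[0] = np.cos(z)
    if nmax >= 1:
        chi[1] = np.cos(z) / z + np.sin(z)
        for n in range(2, nmax + 1):
            chi[n] = (2 * n - 1) / z * chi[n - 1] - chi[n - 2]
    dpsi = np.zeros(nmax + 1)
    dchi = np.zeros(nmax + 1)
    dpsi[0] = np.cos(z)
    dchi[0] = -np.sin(z)
    dpsi[1:] = psi[:-1] - n_idx[1:] / z * psi[1:]
    dchi[1:] = chi[:-1] - n_idx[1:] / z * chi[1:]
    return psi, chi, dpsi, dchi


def coated_sphere_efficiencies(m_core: float, m_shell: float, x_core: float, x_total: float) -> tuple[float, float, float]:
    """``(Qext, Qsca, g)`` for a concentric coated sphere with real indices.

    ``x_core`` and ``x_total`` are the size parameters of the core and of the
    whole (core + shell) sphere. Reduces to the homogeneous result when the
    core and shell indices coincide.
    """
    if not (0 < x_core <= x_total):
        raise ValueError("need 0 < x_core <= x_total")
    m1, m2, x, y = float(m_core), float(m_shell), float(x_core), float(x_total)
    nmax = _nstop(y)
    p1x, _, dp1x, _ = _psi_chi(m1 * x, nmax)
    p2x, c2x, dp2x, dc2x = _psi_chi(m2 * x, nmax)
    p2y, c2y, dp2y, dc2y = _psi_chi(m2 * y, nmax)
    py, cy, dpy, dcy = _psi_chi(y, nmax)
    n = np.arange(1, nmax + 1)
    sl = slice(1, nmax + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        An = (m2 * p2x[sl] * dp1x[sl] - m1 * dp2x[sl] * p1x[sl]) / (
            m2 * c2x[sl] * dp1x[sl] - m1 * dc2x[sl] * p1x[sl]
        )
        Bn = (m2 * dp2x[sl] * p1x[sl] - m1 * p2x[sl] * dp1x[sl]) / (
            m2 * dc2x[sl] * p1x[sl] - m1 * c2x[sl] * dp1x[sl]
        )
    An = np.nan_to_num(An)
    Bn = np.nan_to_num(Bn)
    fa = dp2y[sl] - An * dc2y[sl]
    ga = p2y[sl] - An * c2y[sl]
    fb = dp2y[sl] - Bn * dc2y[sl]
    gb = p2y[sl] - Bn * c2y[sl]
    xiy = py[sl] - 1j * cy[sl]
    dxiy = dpy[sl] - 1j * dcy[sl]
    a = (py[sl] * fa - m2 * dpy[sl] * ga) / (xiy * fa - m2 * dxiy * ga)
    b = (m2 * py[sl] * fb - dpy[sl] * gb) / (m2 * xiy * fb - dxiy * gb)
    nf = n.astype(float)
    qext = (2.0 / y**2) * np.sum((2 * nf + 1) * (a.real + b.real))
    qsca = (2.0 / y**2) * np.sum((2 * nf + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    asy = np.sum(
        nf[:-1] * (nf[:-1] + 2) / (nf[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    )
    asy += np.sum((2 * nf + 1) / (nf * (nf + 1)) * (a * np.conj(b)).real)
    g = (4.0 / (y**2 * qsca)) * asy if qsca > 0 else 0.0
    return float(qext), float(qsca), float(g)


def mie_sphere(
    radius_um: float,
    wavelength_nm: float,
    n_sphere: complex,
    n_medium: float,
    shell_um: float | None = None,
    n_shell: float | None = None,
) -> tuple[float, float]:
    """``(Qsca, g)`` for a sphere of given radius in a host medium.

    With ``shell_um``/``n_shell`` set, a concentric shell of that thickness and
    index is added on top of the core radius (real indices only in that mode).
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    lam_um = wavelength_nm * 1e-3
    x = 2.0 * np.pi * radius_um * n_medium / lam_um
    if shell_um is None:
        m = complex(n_sphere) / n_medium
        _, qsca, g = mie_efficiencies(m, x)
    else:
        if n_shell is None:
            raise ValueError("shell mode requires n_shell")
        y = 2.0 * np.pi * (radius_um + shell_um) * n_medium / lam_um
        _, qsca, g = coated_sphere_efficiencies(
            float(np.real(n_sphere)) / n_medium, float(n_shell) / n_medium, x, y
        )
    return float(qsca), float(g)
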