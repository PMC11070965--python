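"""Independent reference implementations used only by the test suite.

Each oracle takes a numerical route disjoint from the package's own:
scipy spherical Bessel functions instead of recurrences for Mie series,
iterative bounce relaxation instead of closed-form stacking for the cuvette,
a separate vectorized NumPy photon walk for transport, and explicit Python
loops for the mixture weighting.
"""

from __future__ import annotations

import numpy as np
from scipy.special import spherical_jn, spherical_yn


# ---------------------------------------------------------------- Mie series
def _psi(n, z):
    return z * spherical_jn(n, z)


def _dpsi(n, z):
    return spherical_jn(n, z) + z * spherical_jn(n, z, derivative=True)


def _chi(n, z):
    return -z * spherical_yn(n, z)


def _dchi(n, z):
    return -(spherical_yn(n, z) + z * spherical_yn(n, z, derivative=True))


def _xi(n, z):
    return _psi(n, z) - 1j * _chi(n, z)


def _dxi(n, z):
    return _dpsi(n, z) - 1j * _dchi(n, z)


def mie_solid_oracle(x: float, m: complex, nmax: int):
    """Brute-force Lorenz-Mie sums with scipy Bessel functions.

    Complex ``m`` is supported through the complex-argument spherical Bessel
    evaluation.  ``nmax`` should be set to about twice the standard
    truncation order for an oracle-grade tail.
    """
    n = np.arange(1, nmax + 1)
    mx = np.complex128(m * x)
    a = (m * _psi(n, mx) * _dpsi(n, x) - _psi(n, x) * _dpsi(n, mx)) / (
        m * _psi(n, mx) * _dxi(n, x) - _xi(n, x) * _dpsi(n, mx)
    )
    b = (_psi(n, mx) * _dpsi(n, x) - m * _psi(n, x) * _dpsi(n, mx)) / (
        _psi(n, mx) * _dxi(n, x) - m * _xi(n, x) * _dpsi(n, mx)
    )
    qs = 2 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    qe = 2 / x**2 * np.sum((2 * n + 1) * (a + b).real)
    g1 = np.sum(
        n[:-1]
        * (n[:-1] + 2)
        / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    )
    g2 = np.sum((2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real)
    g = 4 / x**2 * (g1 + g2) / qs if qs > 0 else 0.0
    return float(qs), float(qe), float(g)


def mie_coated_oracle(xc: float, y: float, m1: float, m2: float, nmax: int):
    """Two-layer (Aden-Kerker) coefficients evaluated with scipy Bessel
    functions; real indices only."""
    n = np.arange(1, nmax + 1)
    u1, u2, v2 = m1 * xc, m2 * xc, m2 * y
    An = (m2 * _psi(n, u2) * _dpsi(n, u1) - m1 * _dpsi(n, u2) * _psi(n, u1)) / (
        m2 * _chi(n, u2) * _dpsi(n, u1) - m1 * _dchi(n, u2) * _psi(n, u1)
    )
    Bn = (m2 * _psi(n, u1) * _dpsi(n, u2) - m1 * _psi(n, u2) * _dpsi(n, u1)) / (
        m2 * _dchi(n, u2) * _psi(n, u1) - m1 * _dpsi(n, u1) * _chi(n, u2)
    )
    pa = _dpsi(n, v2) - An * _dchi(n, v2)
    qa = _psi(n, v2) - An * _chi(n, v2)
    a = (_psi(n, y) * pa - m2 * _dpsi(n, y) * qa) / (
        _xi(n, y) * pa - m2 * _dxi(n, y) * qa
    )
    pb = _dpsi(n, v2) - Bn * _dchi(n, v2)
    qb = _psi(n, v2) - Bn * _chi(n, v2)
    b = (m2 * _psi(n, y) * pb - _dpsi(n, y) * qb) / (
        m2 * _xi(n, y) * pb - _dxi(n, y) * qb
    )
    qs = 2 / y**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    qe = 2 / y**2 * np.sum((2 * n + 1) * (a + b).real)
    return float(qs), float(qe)


# ------------------------------------------------------------ cuvette stack
def cuvette_bounce_oracle(
    R: list[float], t: list[float], n_iters: int = 400
) -> float:
    """Transmittance of a 4-interface stack by fixed-point bounce iteration.

    ``R[k]`` is the reflectance of interface k (k = 0..3), ``t[j]`` the
    internal transmittance of the gap between interfaces j and j+1
    (wall, medium, wall).  F[k]/B[k] are the right-/left-moving fluxes
    incident on interface k; each sweep adds one bounce order, so many
    sweeps enumerate all multiple-reflection paths to machine precision.
    """
    n_if = len(R)
    F = np.zeros(n_if)
    B = np.zeros(n_if)
    for _ in range(n_iters):
        F_new = np.zeros(n_if)
        B_new = np.zeros(n_if)
        F_new[0] = 1.0  # the source beam
        for k in range(1, n_if):
            F_new[k] = t[k - 1] * (F[k - 1] * (1 - R[k - 1]) + B[k - 1] * R[k - 1])
        for k in range(n_if - 1):
            B_new[k] = t[k] * (B[k + 1] * (1 - R[k + 1]) + F[k + 1] * R[k + 1])
        if np.allclose(F_new, F, rtol=0.0, atol=1e-17) and np.allclose(
            B_new, B, rtol=0.0, atol=1e-17
        ):
            F, B = F_new, B_new
            break
        F, B = F_new, B_new
    return float(F[-1] * (1 - R[-1]))


# ---------------------------------------------------------------- transport
def semi_infinite_mc_oracle(
    mu_a: float, mu_s: float, g: float, n_photons: int, seed: int
) -> float:
    """Vectorized weighted photon walk, matched boundary, semi-infinite.

    Tracks only depth z and direction cosine uz (the azimuthal marginal of
    the scattering rotation is exact for plane-parallel tallies).
    """
    rng = np.random.default_rng(seed)
    mt = mu_a + mu_s
    albedo = mu_s / mt
    z = np.zeros(n_photons)
    uz = np.ones(n_photons)
    w = np.ones(n_photons)
    alive = np.ones(n_photons, dtype=bool)
    rd = 0.0
    while alive.any():
        idx = np.nonzero(alive)[0]
        s = -np.log(rng.random(idx.size)) / mt
        znew = z[idx] + s * uz[idx]
        esc = znew < 0
        rd += w[idx[esc]].sum()
        alive[idx[esc]] = False
        idx = idx[~esc]
        z[idx] = znew[~esc]
        w[idx] *= albedo
        if g == 0:
            uz[idx] = 2 * rng.random(idx.size) - 1
        else:
            u = rng.random(idx.size)
            tmp = (1 - g * g) / (1 - g + 2 * g * u)
            ct = np.clip((1 + g * g - tmp * tmp) / (2 * g), -1.0, 1.0)
            st = np.sqrt(1 - ct**2)
            suz = np.sqrt(np.clip(1 - uz[idx] ** 2, 0, 1))
            phi = 2 * np.pi * rng.random(idx.size)
            uz[idx] = np.clip(uz[idx] * ct + suz * st * np.cos(phi), -1.0, 1.0)
        low = alive & (w < 1e-4)
        if low.any():
            kill = low & (rng.random(n_photons) >= 0.1)
            w[low & ~kill] *= 10.0
            alive &= ~kill
    return rd / n_photons


#: exact Chandrasekhar H-function plane albedo, isotropic scattering,
#: albedo 0.9, matched semi-infinite medium, normal incidence
ISOTROPIC_A09_REFLECTANCE = 0.41495
#: van de Hulst (1980) tabulation: slab of optical depth 2, albedo 0.9,
#: g = 0.75, matched boundaries
VDH_SLAB_RD = 0.09739
VDH_SLAB_TT = 0.66096
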