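"""Lorenz-Mie efficiencies for solid and core-shell (hollow) spheres in a host.

The host medium is handled by the relative-index convention: the size
parameter is x = pi * d * n_host / lambda and all indices are divided by
n_host.  The solid-sphere solver uses a downward recurrence for the
logarithmic derivative (stable for complex indices) with upward Riccati-Bessel
psi/chi recurrences; truncation order follows n_max = ceil(x + 4 x^(1/3) + 2).

The coated-sphere solver implements the classic two-layer (Aden-Kerker)
coefficients in the Bohren & Huffman formulation.  It is exercised here with
real (non-absorbing) indices; strongly absorbing shells at large size
parameters are outside its validated regime.  It returns Qs and Qext only —
the scattering anisotropy of hollow spheres is approximated elsewhere by the
equivalent air-bubble surrogate (see :mod:`phantomlab.mixture`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numba import njit

from .errors import ContractError, ParameterError, UnsupportedRegimeError

#: size parameter above which the series is not evaluated
X_MAX = 5.0e4


@dataclass(frozen=True)
class SphereSpec:
    """Geometry and material identifiers of one (possibly hollow) sphere."""

    outer_diameter_um: float
    wall_thickness_um: Union[float, str, None] = "solid"
    core_material: str = "air"
    shell_material: str = "silica"
    host_material: str = "siliglass"

    def __post_init__(self) -> None:
        if self.outer_diameter_um <= 0:
            raise ParameterError("outer diameter must be positive")
        if not self.is_solid:
            t = float(self.wall_thickness_um)  # type: ignore[arg-type]
            if not (0 < t <= self.outer_diameter_um / 2):
                raise ParameterError(
                    "wall thickness must lie in (0, outer_diameter/2]"
                )

    @property
    def is_solid(self) -> bool:
        return self.wall_thickness_um in ("solid", None)

    @property
    def core_diameter_um(self) -> float:
        if self.is_solid:
            return 0.0
        return self.outer_diameter_um - 2.0 * float(self.wall_thickness_um)  # type: ignore[arg-type]


@dataclass(frozen=True)
class MieResult:
    """Scattering/extinction efficiencies and asymmetry parameter <cos theta>."""

    Qs: float
    Qext: float
    g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.Qs < 0:
            raise ParameterError("Qs must be non-negative")
        if self.g is not None and abs(self.g) > 1 + 1e-12:
            raise ParameterError("g must lie in [-1, 1]")


def _n_max(x: float) -> int:
    return int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


@njit(cache=True)
def _solid_kernel(x: float, m: complex, nmax: int):  # pragma: no cover - jitted
    """Return (Qs, Qext, g) for a homogeneous sphere, size parameter x."""
    mx = m * x
    # downward log-derivative start: clear both nmax and |mx| by an
    # Airy-regime margin so the seed error fully contracts before n ~ |mx|
    margin = 16 + int((40.0 * math.sqrt(max(abs(mx), 1.0))) ** (2.0 / 3.0))
    nstart = max(nmax, int(abs(mx))) + margin
    # downward recurrence for the logarithmic derivative D_n(mx)
    D = np.zeros(nstart + 1, dtype=np.complex128)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)

    psi_prev = math.cos(x)  # psi_{n-2} during the loop (psi_{-1} at start)
    psi = math.sin(x)  # psi_{n-1} (psi_0 at start)
    chi_prev = -math.sin(x)
    chi = math.cos(x)

    qext = 0.0
    qsca = 0.0
    gsum = 0.0
    a_prev = 0.0 + 0.0j
    b_prev = 0.0 + 0.0j
    for n in range(1, nmax + 1):
        psi_n = (2.0 * n - 1.0) / x * psi - psi_prev
        chi_n = (2.0 * n - 1.0) / x * chi - chi_prev
        xi_n = complex(psi_n, -chi_n)
        xi_nm1 = complex(psi, -chi)
        Dn = D[n]
        fa = Dn / m + n / x
        fb = Dn * m + n / x
        a = (fa * psi_n - psi) / (fa * xi_n - xi_nm1)
        b = (fb * psi_n - psi) / (fb * xi_n - xi_nm1)
        f = 2.0 * n + 1.0
        qext += f * (a.real + b.real)
        qsca += f * (abs(a) ** 2 + abs(b) ** 2)
        if n >= 2:
            k = n - 1.0
            gsum += (
                k * (k + 2.0) / (k + 1.0)
                * (a_prev * np.conj(a) + b_prev * np.conj(b)).real
            )
        gsum += f / (n * (n + 1.0)) * (a * np.conj(b)).real
        a_prev = a
        b_prev = b
        psi_prev = psi
        psi = psi_n
        chi_prev = chi
        chi = chi_n

    qext *= 2.0 / (x * x)
    qsca *= 2.0 / (x * x)
    if qsca > 0.0:
        g = (4.0 / (x * x)) * gsum / qsca
    else:
        g = 0.0
    return qsca, qext, g


@njit(cache=True)
def _riccati_psi(z: complex, nmax: int):  # pragma: no cover - jitted
    """psi_0..psi_nmax by downward recurrence (stable for n > |z|).

    The unnormalized downward pass is rescaled whenever it threatens to
    overflow; the whole (linear) solution is then pinned to psi_0 = sin z.
    The start order clears both nmax and |z| by an Airy-regime margin
    ~(40 sqrt(z))^(2/3), which is what Miller's algorithm needs for the
    minimal solution to dominate to double precision near n ~ z.
    """
    az = abs(z)
    margin = 15 + int((40.0 * math.sqrt(max(az, 1.0))) ** (2.0 / 3.0))
    M = max(nmax, int(az)) + margin
    arr = np.zeros(M + 2, dtype=np.complex128)
    arr[M + 1] = 0.0
    arr[M] = 1.0e-30
    for n in range(M, 0, -1):
        arr[n - 1] = (2.0 * n + 1.0) / z * arr[n] - arr[n + 1]
        if abs(arr[n - 1]) > 1.0e250:
            for k in range(n - 1, M + 2):
                arr[k] *= 1.0e-250
    # pin to psi_0 = sin z or psi_1 = sin z / z - cos z, whichever is larger:
    # normalizing at a near-zero of psi_0 would amplify the seed error
    s0 = np.sin(z)
    s1 = s0 / z - np.cos(z)
    if abs(s0) >= abs(s1):
        scale = s0 / arr[0]
    else:
        scale = s1 / arr[1]
    return arr[: nmax + 1] * scale


@njit(cache=True)
def _riccati_chi(z: complex, nmax: int):  # pragma: no cover - jitted
    """chi_0..chi_nmax by upward recurrence (always stable); capped at 1e250.

    Returns (chi, n_dead): entries at orders >= n_dead overflowed and are
    clamped; callers must treat those orders as core-free.
    """
    chi = np.zeros(nmax + 1, dtype=np.complex128)
    prev = -np.sin(z)  # chi_{-1}
    chi[0] = np.cos(z)
    n_dead = nmax + 1
    for n in range(1, nmax + 1):
        cur = (2.0 * n - 1.0) / z * chi[n - 1] - prev
        prev = chi[n - 1]
        if abs(cur) > 1.0e250:
            n_dead = n
            for k in range(n, nmax + 1):
                chi[k] = 1.0e250
            break
        chi[n] = cur
    return chi, n_dead


@njit(cache=True)
def _coated_kernel(xc: float, y: float, m1: complex, m2: complex, nmax: int):  # pragma: no cover
    """Return (Qs, Qext) for a core-shell sphere.

    xc/y: core/outer size parameters; m1/m2: core/shell indices relative to
    the host.  Two-layer Aden-Kerker coefficients in the Bohren & Huffman
    formulation; psi by downward recurrence, chi upward.  The core terms
    A_n, B_n are forced to zero once the core chi functions overflow (the
    correct vanishing-core limit).
    """
    u1 = m1 * xc  # core argument
    u2 = m2 * xc  # shell argument at the core radius
    v2 = m2 * y  # shell argument at the outer radius
    zy = complex(y, 0.0)

    psi_u1 = _riccati_psi(u1, nmax)
    psi_u2 = _riccati_psi(u2, nmax)
    psi_v2 = _riccati_psi(v2, nmax)
    psi_y = _riccati_psi(zy, nmax)
    chi_u1, dead1 = _riccati_chi(u1, nmax)
    chi_u2, dead2 = _riccati_chi(u2, nmax)
    chi_v2, dead_v = _riccati_chi(v2, nmax)
    chi_y, dead_y = _riccati_chi(zy, nmax)
    n_core_dead = min(dead1, dead2)

    qext = 0.0
    qsca = 0.0
    for n in range(1, nmax + 1):
        dpsi_u1 = psi_u1[n - 1] - n / u1 * psi_u1[n]
        dpsi_u2 = psi_u2[n - 1] - n / u2 * psi_u2[n]
        dchi_u2 = chi_u2[n - 1] - n / u2 * chi_u2[n]
        dpsi_v2 = psi_v2[n - 1] - n / v2 * psi_v2[n]
        dchi_v2 = chi_v2[n - 1] - n / v2 * chi_v2[n]
        dpsi_y = psi_y[n - 1] - n / zy * psi_y[n]
        dchi_y = chi_y[n - 1] - n / zy * chi_y[n]

        An = 0.0 + 0.0j
        Bn = 0.0 + 0.0j
        if n < n_core_dead:
            An_num = m2 * psi_u2[n] * dpsi_u1 - m1 * dpsi_u2 * psi_u1[n]
            An_den = m2 * chi_u2[n] * dpsi_u1 - m1 * dchi_u2 * psi_u1[n]
            Bn_num = m2 * psi_u1[n] * dpsi_u2 - m1 * psi_u2[n] * dpsi_u1
            Bn_den = m2 * dchi_u2 * psi_u1[n] - m1 * dpsi_u1 * chi_u2[n]
            if abs(An_den) > 0.0:
                An = An_num / An_den
            if abs(Bn_den) > 0.0:
                Bn = Bn_num / Bn_den
            if not (
                np.isfinite(An.real)
                and np.isfinite(An.imag)
                and np.isfinite(Bn.real)
                and np.isfinite(Bn.imag)
            ):
                An = 0.0 + 0.0j
                Bn = 0.0 + 0.0j

        xi_y = psi_y[n] - 1j * chi_y[n]
        dxi_y = dpsi_y - 1j * dchi_y

        pa = dpsi_v2 - An * dchi_v2
        qa = psi_v2[n] - An * chi_v2[n]
        a = (psi_y[n] * pa - m2 * dpsi_y * qa) / (xi_y * pa - m2 * dxi_y * qa)
        pb = dpsi_v2 - Bn * dchi_v2
        qb = psi_v2[n] - Bn * chi_v2[n]
        b = (m2 * psi_y[n] * pb - dpsi_y * qb) / (m2 * xi_y * pb - dxi_y * qb)

        f = 2.0 * n + 1.0
        qext += f * (a.real + b.real)
        qsca += f * (abs(a) ** 2 + abs(b) ** 2)

    qext *= 2.0 / (y * y)
    qsca *= 2.0 / (y * y)
    return qsca, qext


def size_parameter(diameter_um: float, wavelength_nm: float, n_host: float) -> float:
    """x = pi * d * n_host / lambda, with lambda converted to um."""
    return math.pi * diameter_um * n_host / (wavelength_nm / 1.0e3)


def mie_solid(
    diameter_um: float,
    wavelength_nm: float,
    n_sphere: complex,
    n_host: float,
) -> MieResult:
    """Efficiencies and asymmetry parameter of a homogeneous sphere in a host."""
    if diameter_um <= 0 or wavelength_nm <= 0:
        raise ParameterError("diameter and wavelength must be positive")
    if n_host <= 0:
        raise ParameterError("host index must be positive")
    x = size_parameter(diameter_um, wavelength_nm, n_host)
    if x > X_MAX:
        raise UnsupportedRegimeError(
            f"size parameter {x:.3g} exceeds supported maximum {X_MAX:.0e}"
        )
    m = complex(n_sphere) / n_host
    qs, qext, g = _solid_kernel(x, m, _n_max(x))
    return MieResult(Qs=max(qs, 0.0), Qext=qext, g=min(max(g, -1.0), 1.0))


def mie_coated(
    sphere: SphereSpec,
    wavelength_nm: float,
    n_core: complex,
    n_shell: complex,
    n_host: float,
) -> MieResult:
    """Efficiencies of a two-layer (core-shell) sphere; anisotropy not computed."""
    if sphere.is_solid:
        raise ContractError("sphere is solid; use mie_solid")
    if wavelength_nm <= 0 or n_host <= 0:
        raise ParameterError("wavelength and host index must be positive")
    d_core = sphere.core_diameter_um
    if d_core <= 0:
        raise ContractError(
            "wall thickness consumes the whole radius; use mie_solid on the shell material"
        )
    y = size_parameter(sphere.outer_diameter_um, wavelength_nm, n_host)
    xc = size_parameter(d_core, wavelength_nm, n_host)
    if y > X_MAX:
        raise UnsupportedRegimeError(
            f"size parameter {y:.3g} exceeds supported maximum {X_MAX:.0e}"
        )
    m1 = complex(n_core) / n_host
    m2 = complex(n_shell) / n_host
    if xc < 1.0e-3:
        # core far below the Rayleigh floor: homogeneous shell-material sphere
        qs, qext, _ = _solid_kernel(y, m2, _n_max(y))
    else:
        qs, qext = _coated_kernel(xc, y, m1, m2, _n_max(y))
    return MieResult(Qs=max(qs, 0.0), Qext=qext, g=None)


def cross_section(diameter_um: float, Qs: float) -> float:
    """Scattering cross-section Cs = (pi d^2 / 4) * Qs, in um^2."""
    if diameter_um < 0 or Qs < 0:
        raise ParameterError("diameter and Qs must be non-negative")
    return math.pi * diameter_um**2 / 4.0 * Qs
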