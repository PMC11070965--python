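"""Photon-packet Monte Carlo radiative transport in layered media.

A CPU re-implementation of the classic multi-layer photon-packet scheme
(MCML semantics): packets launched normally onto a plane-parallel stack,
specular deduction at entry, exponential step sampling, fractional weight
deposition mu_a/mu_t per interaction, Henyey-Greenstein direction updates,
Fresnel reflection/refraction (with total internal reflection) at layer
boundaries, and Russian roulette termination.  Only spatially integrated
tallies are kept — diffuse reflectance, transmittance and absorbed fraction —
because the fit target is a spatially averaged spectrum.

Determinism: the jitted kernel seeds its own generator, so identical
(layers, n_photons, seed) give bit-identical tallies.  Spectral runs derive
one substream seed per wavelength from (seed, index); reusing the same base
seed across optimizer iterations yields common random numbers, making the
least-squares objective a deterministic function of the optical properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from numba import njit

from .errors import ConfigurationError, ParameterError
from .mixture import OpticalProperties
from .spectra import Spectrum

#: slab thickness used to realize "semi-infinite" layers, cm
SEMI_INFINITE_CM = 1.0e9
#: Russian roulette: threshold weight and survival probability
ROULETTE_THRESHOLD = 1.0e-4
ROULETTE_SURVIVAL = 0.1
#: hard per-photon step cap: a zero-absorption matched semi-infinite walk has
#: an infinite-mean return time, so runaway packets are tallied as absorbed
MAX_STEPS_PER_PHOTON = 1_000_000


@dataclass(frozen=True)
class Layer:
    """One plane-parallel layer: thickness [cm] and scalar optical properties."""

    thickness_cm: float
    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ParameterError("layer thickness must be positive")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ParameterError("mu_a and mu_s must be non-negative")
        if not (-1 < self.g < 1):
            raise ParameterError("g must lie in (-1, 1)")
        if self.n < 1:
            raise ParameterError("n must be >= 1")

    @classmethod
    def semi_infinite(cls, mu_a: float, mu_s: float, g: float, n: float) -> "Layer":
        return cls(SEMI_INFINITE_CM, mu_a, mu_s, g, n)


@dataclass(frozen=True)
class TransportResult:
    """Normalized tallies of one simulation; each lies in [0, 1]."""

    diffuse_reflectance: float
    specular_reflectance: float
    absorbed_fraction: float
    transmitted_fraction: float
    n_photons: int
    seed: int
    low_photon_warning: bool = False

    @property
    def total(self) -> float:
        return (
            self.diffuse_reflectance
            + self.specular_reflectance
            + self.absorbed_fraction
            + self.transmitted_fraction
        )

    def std_error(self, tally: float) -> float:
        """Binomial-style standard error of a tally at this photon count."""
        p = min(max(tally, 0.0), 1.0)
        return math.sqrt(max(p * (1.0 - p), 1.0 / self.n_photons) / self.n_photons)


@njit(cache=True, fastmath=True)
def _hg_cos(g: float, u: float) -> float:  # pragma: no cover - jitted
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


def hg_sample(g: float, u: float) -> float:
    """Closed-form inverse-CDF sample of cos(theta) for Henyey-Greenstein."""
    if not (-1 < g < 1):
        raise ParameterError("g must lie in (-1, 1)")
    if not (0 <= u < 1):
        raise ParameterError("u must lie in [0, 1)")
    return float(_hg_cos(g, u))


@njit(cache=True, fastmath=True)
def _fresnel(n1: float, n2: float, ca1: float):  # pragma: no cover - jitted
    """Unpolarized Fresnel reflectance and transmitted cosine (ca1 = |cos i|)."""
    if n1 == n2:
        return 0.0, ca1
    if ca1 > 1.0 - 1.0e-12:  # normal incidence
        r = (n2 - n1) / (n2 + n1)
        return r * r, 1.0
    sa1 = math.sqrt(1.0 - ca1 * ca1)
    sa2 = n1 * sa1 / n2
    if sa2 >= 1.0:  # total internal reflection
        return 1.0, 0.0
    ca2 = math.sqrt(1.0 - sa2 * sa2)
    cap = ca1 * ca2 - sa1 * sa2  # cos(a1 + a2) terms via angle sums
    cam = ca1 * ca2 + sa1 * sa2
    sap = sa1 * ca2 + ca1 * sa2
    sam = sa1 * ca2 - ca1 * sa2
    r = 0.5 * sam * sam * (cam * cam + cap * cap) / (sap * sap * cam * cam)
    return r, ca2


@njit(cache=True, fastmath=True)
def _mc_kernel(
    thick: np.ndarray,
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    gs: np.ndarray,
    ns: np.ndarray,
    n_ambient: float,
    n_photons: int,
    seed: int,
):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_layers = thick.size
    z_top = np.zeros(n_layers)
    for i in range(1, n_layers):
        z_top[i] = z_top[i - 1] + thick[i - 1]
    z_bot_last = z_top[n_layers - 1] + thick[n_layers - 1]

    # specular reflection at the ambient/top interface, normal incidence
    r0 = (n_ambient - ns[0]) / (n_ambient + ns[0])
    rsp = r0 * r0

    rd = 0.0
    tt = 0.0
    ab = 0.0
    for _ in range(n_photons):
        w = 1.0 - rsp
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        alive = True
        s = 0.0  # remaining dimensionless step
        n_steps = 0
        while alive:
            n_steps += 1
            if n_steps > MAX_STEPS_PER_PHOTON:
                ab += w
                break
            mt = mu_a[layer] + mu_s[layer]
            if s <= 0.0:
                s = -math.log(np.random.random() + 1.0e-300)
            # distance to the boundary along uz
            if uz > 1.0e-12:
                zb = z_top[layer] + thick[layer]
                db = (zb - z) / uz
            elif uz < -1.0e-12:
                zb = z_top[layer]
                db = (zb - z) / uz
            else:
                db = 1.0e30
            step = s / mt if mt > 0.0 else 1.0e30
            if db < step:  # hit the boundary first
                z += db * uz
                if mt > 0.0:
                    s -= db * mt
                going_up = uz < 0.0
                if going_up:
                    n2 = n_ambient if layer == 0 else ns[layer - 1]
                else:
                    n2 = n_ambient if layer == n_layers - 1 else ns[layer + 1]
                r, ca2 = _fresnel(ns[layer], n2, abs(uz))
                if np.random.random() > r:  # transmit / refract
                    ratio = ns[layer] / n2
                    ux *= ratio
                    uy *= ratio
                    uz = ca2 if uz > 0.0 else -ca2
                    if going_up:
                        if layer == 0:
                            rd += w
                            alive = False
                        else:
                            layer -= 1
                    else:
                        if layer == n_layers - 1:
                            tt += w
                            alive = False
                        else:
                            layer += 1
                else:  # reflect
                    uz = -uz
                continue
            # interaction inside the layer
            z += step * uz
            s = 0.0
            dw = w * mu_a[layer] / mt
            ab += dw
            w -= dw
            # scatter: Henyey-Greenstein polar angle, uniform azimuth
            ct = _hg_cos(gs[layer], np.random.random())
            st = math.sqrt(max(1.0 - ct * ct, 0.0))
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                uxn = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uyn = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uzn = -st * cp * den + uz * ct
                ux, uy, uz = uxn, uyn, uzn
            if w < ROULETTE_THRESHOLD:
                if np.random.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    alive = False
    inv = 1.0 / n_photons
    return rd * inv, rsp, ab * inv, tt * inv


def simulate_reflectance(
    layers: List[Layer],
    ambient_n: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 0,
) -> TransportResult:
    """Run the photon-packet simulation on a layer stack; deterministic in seed."""
    if not layers:
        raise ConfigurationError("need at least one layer")
    if ambient_n < 1:
        raise ParameterError("ambient index must be >= 1")
    if n_photons < 1:
        raise ParameterError("n_photons must be positive")
    warn = n_photons < 1_000
    thick = np.array([l.thickness_cm for l in layers])
    mu_a = np.array([l.mu_a for l in layers])
    mu_s = np.array([l.mu_s for l in layers])
    gs = np.array([l.g for l in layers])
    ns = np.array([l.n for l in layers])
    if np.all(mu_a + mu_s == 0) and len(layers) > 1:
        raise ConfigurationError("stack is entirely clear; nothing to simulate")
    rd, rsp, ab, tt = _mc_kernel(
        thick, mu_a, mu_s, gs, ns, float(ambient_n), int(n_photons), int(seed) % 2**31
    )
    return TransportResult(
        diffuse_reflectance=rd,
        specular_reflectance=rsp,
        absorbed_fraction=ab,
        transmitted_fraction=tt,
        n_photons=int(n_photons),
        seed=int(seed),
        low_photon_warning=warn,
    )


def substream_seed(base_seed: int, index: int) -> int:
    """Reproducible per-wavelength substream seed below 2^31."""
    ss = np.random.SeedSequence(entropy=[int(base_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)


#: default dimensionless kill rate of the scaled (path-length) simulation:
#: photons are terminated by an exponential absorption budget ~ Exp(rate),
#: later compensated exactly in the estimator weights.
PATH_KILL_RATE = 1.0e-3
_PATH_MAX_STEPS = 200_000


@njit(cache=True, fastmath=True)
def _paths_kernel(
    g: float,
    n_medium: float,
    n_ambient: float,
    n_photons: int,
    seed: int,
    kill_rate: float,
):  # pragma: no cover - jitted
    """Scattering-only semi-infinite walk; returns dimensionless path to
    escape (units of 1/mu_s) per photon, or -1 if terminated before escape."""
    np.random.seed(seed)
    out = np.empty(n_photons)
    for i in range(n_photons):
        s_budget = -math.log(np.random.random() + 1.0e-300) / kill_rate
        s_tot = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        res = -1.0
        for _ in range(_PATH_MAX_STEPS):
            step = -math.log(np.random.random() + 1.0e-300)
            if uz < 0.0 and z + step * uz < 0.0:  # would cross the surface
                db = -z / uz
                if s_tot + db > s_budget:
                    break  # absorbed en route to the boundary
                r, ca2 = _fresnel(n_medium, n_ambient, abs(uz))
                if np.random.random() > r:
                    res = s_tot + db
                    break
                # internal reflection: bounce at the surface, keep walking
                s_tot += db
                z = 0.0
                uz = -uz
                step -= db
            if s_tot + step > s_budget:
                break
            s_tot += step
            z += step * uz
            ct = _hg_cos(g, np.random.random())
            st = math.sqrt(max(1.0 - ct * ct, 0.0))
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                uxn = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uyn = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uzn = -st * cp * den + uz * ct
                ux, uy, uz = uxn, uyn, uzn
        out[i] = res
    return out


@dataclass(frozen=True)
class SemiInfinitePathSet:
    """Cached scattering-only paths of a semi-infinite medium at one wavelength.

    Because the medium is homogeneous and semi-infinite, absorption enters
    the diffuse reflectance only through exp(-mu_a * L) along each escaping
    path, and mu_s only rescales path lengths; one scattering simulation at
    fixed (g, n) therefore yields R_d for every (mu_a, mu_s) pair (the
    classic scaled / "white" Monte Carlo).  The early-termination kill rate
    used during simulation is compensated exactly in the weights.
    """

    escape_paths: np.ndarray  # dimensionless path lengths of escaping photons
    n_photons: int
    kill_rate: float
    specular: float
    seed: int

    def contributions(self, mu_a: float, mu_s: float) -> np.ndarray:
        """Per-escaping-photon weights of the R_d estimator (others are 0)."""
        if mu_a < 0 or mu_s < 0:
            raise ParameterError("mu_a and mu_s must be non-negative")
        if mu_s <= 0.0:
            return np.zeros(0)
        r = mu_a / mu_s - self.kill_rate
        return (1.0 - self.specular) * np.exp(-r * self.escape_paths)

    def reflectance(self, mu_a: float, mu_s: float) -> float:
        w = self.contributions(mu_a, mu_s)
        return float(w.sum() / self.n_photons)

    def reflectance_se(self, mu_a: float, mu_s: float) -> float:
        """Standard error of the R_d estimate (includes the zero weights)."""
        w = self.contributions(mu_a, mu_s)
        n = self.n_photons
        mean = w.sum() / n
        var = (w @ w) / n - mean**2
        return float(math.sqrt(max(var, 0.0) / n))


def trace_semi_infinite_paths(
    g: float,
    n_medium: float,
    ambient_n: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 0,
    kill_rate: float = PATH_KILL_RATE,
) -> SemiInfinitePathSet:
    """Run the scattering-only walk once; see :class:`SemiInfinitePathSet`."""
    if not (-1 < g < 1):
        raise ParameterError("g must lie in (-1, 1)")
    if n_medium < 1 or ambient_n < 1:
        raise ParameterError("indices must be >= 1")
    if n_photons < 1 or kill_rate <= 0:
        raise ParameterError("n_photons and kill_rate must be positive")
    paths = _paths_kernel(
        float(g),
        float(n_medium),
        float(ambient_n),
        int(n_photons),
        int(seed) % 2**31,
        float(kill_rate),
    )
    r0 = (ambient_n - n_medium) / (ambient_n + n_medium)
    return SemiInfinitePathSet(
        escape_paths=paths[paths >= 0.0],
        n_photons=int(n_photons),
        kill_rate=float(kill_rate),
        specular=float(r0 * r0),
        seed=int(seed),
    )


def spectral_reflectance(
    props: OpticalProperties,
    ambient_n: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 0,
    include_specular: bool = False,
    path_sets: Optional[list] = None,
) -> Spectrum:
    """Diffuse reflectance of a semi-infinite medium at each grid wavelength.

    One scattering-only simulation per wavelength (substream seed derived
    from (seed, index)) evaluated through the scaled-path estimator: with a
    fixed base seed the whole spectrum is a deterministic, smooth function
    of the optical properties (common random numbers), which is what makes
    the inverse fit's least-squares objective well behaved.  Specular
    reflection is excluded by default, matching reflectance normalized to a
    white standard.  ``path_sets`` short-circuits the simulation with
    pre-traced paths (they must match grid length, photons and seeds).
    """
    m = len(props.grid)
    if path_sets is None:
        path_sets = spectral_path_sets(
            props.g, props.n, ambient_n, n_photons, seed
        )
    elif len(path_sets) != m:
        raise ParameterError("path_sets length differs from the grid")
    vals = np.empty(m)
    for i in range(m):
        ps = path_sets[i]
        vals[i] = ps.reflectance(props.mu_a[i], props.mu_s[i])
        if include_specular:
            vals[i] += ps.specular
    return Spectrum(props.grid, np.clip(vals, 0.0, 1.0), kind="reflectance")


def spectral_path_sets(
    g: np.ndarray,
    n: np.ndarray,
    ambient_n: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 0,
    kill_rate: float = PATH_KILL_RATE,
) -> list:
    """Per-wavelength path sets with substream seeds derived from (seed, i)."""
    return [
        trace_semi_infinite_paths(
            float(np.clip(g[i], -0.999999, 0.999999)),
            float(n[i]),
            ambient_n,
            n_photons,
            substream_seed(seed, i),
            kill_rate,
        )
        for i in range(len(g))
    ]
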