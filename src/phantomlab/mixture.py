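"""Bulk optical properties of the polydisperse hollow-microsphere population.

The scattering coefficient of a dilute (non-interacting) suspension of
spheres at volume fraction f_v follows from number density times scattering
cross-section, which for monodisperse spheres of diameter d collapses to

    mu_s = f_v * 3 * Qs / (2 * d).

The population model averages this over the measured diameter distribution
(volume-fraction weights phi_r) and over a box-shaped wall-thickness
distribution ({0.7..1.1} um, weight 0.2 each, from focused-ion-beam
cross-sections).  Spheres whose radius does not exceed the wall thickness are
solid glass; larger ones are air-core/silica-shell particles whose anisotropy
is approximated by the equivalent air bubble (radius minus wall) in the host,
because the coated-sphere solver does not provide <cos theta>.

Linearity in f_v means everything is computed once at unit volume fraction
and rescaled at will.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

from .errors import ParameterError
from .materials import MaterialLibrary
from .mie import SphereSpec, mie_coated, mie_solid
from .sizing import SizeDistribution
from .spectra import Spectrum, SpectralGrid, UM_PER_CM

#: wall thicknesses measured by FIB sectioning: box distribution, um
DEFAULT_WALL_THICKNESSES_UM = (0.7, 0.8, 0.9, 1.0, 1.1)


@dataclass(frozen=True)
class WallThicknessModel:
    """Discrete wall-thickness distribution (um) with normalized weights."""

    thicknesses_um: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_WALL_THICKNESSES_UM)
    )
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.thicknesses_um, dtype=float)
        w = (
            np.full(t.size, 1.0 / t.size)
            if self.weights is None
            else np.asarray(self.weights, dtype=float)
        )
        object.__setattr__(self, "thicknesses_um", t)
        object.__setattr__(self, "weights", w)
        if t.size == 0 or np.any(t <= 0) or not np.all(np.diff(t) > 0):
            raise ParameterError("thicknesses must be positive, strictly increasing")
        if w.shape != t.shape or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class PhantomComposition:
    """Volume fraction of scatterers and fraction of the diluted pigment stock."""

    scatterer_volume_fraction: float
    pigment_fraction: float

    def __post_init__(self) -> None:
        f_s, f_p = self.scatterer_volume_fraction, self.pigment_fraction
        if not (0 <= f_s <= 1 and 0 <= f_p <= 1):
            raise ParameterError("fractions must lie in [0, 1]")
        if f_s + f_p > 1:
            raise ParameterError("fractions must sum to at most 1")


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength mu_a, mu_s [cm^-1], anisotropy g and index n."""

    grid: SpectralGrid
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.grid)
        for name in ("mu_a", "mu_s", "g", "n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (m,):
                raise ParameterError(f"{name} must have length {m}")
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise ParameterError("mu_a and mu_s must be non-negative")
        if np.any(np.abs(self.g) > 1):
            raise ParameterError("g must lie in [-1, 1]")
        if np.any(self.n < 1):
            raise ParameterError("n must be >= 1")


def per_size_mu_s(diameter_um: float, Qs: float, volume_fraction: float) -> float:
    """mu_s [cm^-1] of a monodisperse suspension: f_v * 3 Qs / (2 d)."""
    if diameter_um <= 0:
        raise ParameterError("diameter must be positive")
    if Qs < 0 or volume_fraction < 0 or volume_fraction > 1:
        raise ParameterError("need Qs >= 0 and volume fraction in [0, 1]")
    d_cm = diameter_um / UM_PER_CM
    return volume_fraction * 3.0 * Qs / (2.0 * d_cm)


def interpolate_distribution(
    dist: SizeDistribution, step_um: float = 0.1
) -> SizeDistribution:
    """Resample bin centers to a uniform ``step_um`` grid and renormalize."""
    d = dist.diameters_um
    if d.size == 1:
        return dist
    new_d = np.arange(d[0], d[-1] + step_um / 2, step_um)
    nf = np.interp(new_d, d, dist.number_fraction)
    vf = np.interp(new_d, d, dist.volume_fraction)
    return SizeDistribution(new_d, nf / nf.sum(), vf / vf.sum())


def mixture_optical_props(
    dist: SizeDistribution,
    wall: WallThicknessModel,
    materials: MaterialLibrary,
    grid: SpectralGrid,
    volume_fraction: float,
    g_weighting: Literal["literal", "scattering"] = "literal",
    interp_step_um: float | None = 0.1,
    weight_floor: float = 1e-12,
) -> Tuple[Spectrum, Spectrum]:
    """Population-averaged (mu_s(lambda), g(lambda)) of the sphere mixture.

    Per wall thickness t (weight w_t) and diameter bin d (volume-fraction
    weight phi): radius r = d/2 above t gives a hollow sphere -> coated-sphere
    Qs plus the air-bubble anisotropy surrogate g(2(r - t)); r <= t gives a
    solid glass sphere -> solid Qs and g.  mu_s is the phi- and w_t-weighted
    sum of unit-volume-fraction per-size coefficients, rescaled by
    ``volume_fraction``; g is phi-weighted directly ("literal") or weighted by
    each component's scattering contribution ("scattering").
    """
    if not (0 <= volume_fraction <= 1):
        raise ParameterError("volume fraction must lie in [0, 1]")
    if g_weighting not in ("literal", "scattering"):
        raise ParameterError("g_weighting must be 'literal' or 'scattering'")
    if interp_step_um is not None and dist.diameters_um.size > 1:
        dist = interpolate_distribution(dist, interp_step_um)

    wl = grid.wavelengths
    n_host = materials.refractive_index("siliglass", wl)
    n_shell = materials.refractive_index("silica", wl)
    n_core = materials.refractive_index("air", wl)

    diameters = dist.diameters_um
    phis = dist.volume_fraction
    use = phis > weight_floor
    diameters, phis = diameters[use], phis[use]
    phi_norm = phis.sum()
    if diameters.size == 0:
        raise ParameterError("distribution has no bins above the weight floor")

    mu_s_unit = np.zeros(wl.size)
    g_num = np.zeros(wl.size)
    g_den = np.zeros(wl.size)
    for t, w_t in zip(wall.thicknesses_um, wall.weights):
        for d, phi in zip(diameters, phis):
            phi = phi / phi_norm
            r = d / 2.0
            for k in range(wl.size):
                if r > t:
                    q = mie_coated(
                        SphereSpec(d, t),
                        wl[k],
                        n_core[k],
                        n_shell[k],
                        n_host[k],
                    ).Qs
                    g_k = mie_solid(2.0 * (r - t), wl[k], n_core[k], n_host[k]).g
                else:
                    res = mie_solid(d, wl[k], n_shell[k], n_host[k])
                    q, g_k = res.Qs, res.g
                mu_k = per_size_mu_s(d, q, 1.0)
                mu_s_unit[k] += w_t * phi * mu_k
                if g_weighting == "literal":
                    g_num[k] += w_t * phi * g_k
                    g_den[k] += w_t * phi
                else:
                    g_num[k] += w_t * phi * mu_k * g_k
                    g_den[k] += w_t * phi * mu_k

    g_vals = np.where(g_den > 0, g_num / np.maximum(g_den, 1e-300), 0.0)
    mu_s = Spectrum(grid, volume_fraction * mu_s_unit, kind="mu_s")
    g_spec = Spectrum(grid, np.clip(g_vals, -1.0, 1.0), kind="anisotropy")
    return mu_s, g_spec


def reduced_scattering(mu_s: float | np.ndarray, g: float | np.ndarray):
    """Reduced scattering coefficient mu_s' = (1 - g) * mu_s."""
    mu_s = np.asarray(mu_s, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(mu_s < 0):
        raise ParameterError("mu_s must be non-negative")
    if np.any(np.abs(g) > 1):
        raise ParameterError("g must lie in [-1, 1]")
    out = (1.0 - g) * mu_s
    return float(out) if out.ndim == 0 else out


def mass_to_volume_fraction(w: float, density_ratio: float = 1.196) -> float:
    """Two-component conversion v = (w/rho_r) / (w/rho_r + (1 - w)).

    ``density_ratio`` is rho_scatterer / rho_host; the measured value for the
    silica spheres in the silicone host is 1.196 (+-2.5%).
    """
    if not (0 <= w <= 1):
        raise ParameterError("mass fraction must lie in [0, 1]")
    if density_ratio <= 0:
        raise ParameterError("density ratio must be positive")
    return (w / density_ratio) / (w / density_ratio + (1.0 - w))


def volume_to_mass_fraction(v: float, density_ratio: float = 1.196) -> float:
    """Inverse of :func:`mass_to_volume_fraction`."""
    if not (0 <= v <= 1):
        raise ParameterError("volume fraction must lie in [0, 1]")
    if density_ratio <= 0:
        raise ParameterError("density ratio must be positive")
    return v * density_ratio / (v * density_ratio + (1.0 - v))
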