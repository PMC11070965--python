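"""Collimated cuvette transmittance: forward model and absorption inversion.

The sample sits between two plane-parallel cuvette walls:
air | wall | medium | wall | air.  The forward model treats the stack
incoherently (wall thickness ~1 mm vastly exceeds the source coherence
length): normal-incidence Fresnel reflectances at the four interfaces,
Beer-Lambert attenuation in walls and medium, and the full geometric series
of inter-wall multiple reflections, composed in closed form with the
standard two-beam (Stokes) layer-stacking relations.

Inversion recovers mu_a(lambda) of the medium by a bracketed per-wavelength
root solve of the forward model; a companion routine calibrates the wall
absorption from an empty (air-filled) cuvette measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .spectra import Spectrum


@dataclass(frozen=True)
class CuvetteGeometry:
    """Macro cuvette: medium path, wall thickness, index and wall-loss spectra.

    ``n_wall``/``n_medium`` map wavelengths [nm] to refractive indices;
    ``mu_a_wall`` to the single-wall absorption coefficient [cm^-1].
    Defaults describe a standard 10 mm polystyrene macro cuvette with
    lossless walls.
    """

    inner_path_cm: float = 1.0
    wall_thickness_cm: float = 0.1
    n_wall: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: lambda wl: np.full_like(np.asarray(wl, float), 1.59)
    )
    n_medium: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: lambda wl: np.full_like(np.asarray(wl, float), 1.41)
    )
    mu_a_wall: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: lambda wl: np.zeros_like(np.asarray(wl, float))
    )
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        if self.inner_path_cm <= 0 or self.wall_thickness_cm <= 0:
            raise ParameterError("path lengths must be positive")
        if self.n_ambient < 1:
            raise ParameterError("ambient index must be >= 1")

    @classmethod
    def from_yaml(cls, path, materials=None) -> "CuvetteGeometry":
        """Load geometry from a YAML file with unit-explicit keys.

        Recognized keys: ``inner_path_cm``, ``wall_thickness_cm``,
        ``n_ambient`` plus either constant values (``n_wall``, ``n_medium``,
        ``mu_a_wall_per_cm``) or material names (``wall_material``,
        ``medium_material``) resolved against ``materials``.
        """
        import yaml

        cfg = yaml.safe_load(open(path)) or {}
        kwargs: dict = {}
        for key in ("inner_path_cm", "wall_thickness_cm", "n_ambient"):
            if key in cfg:
                kwargs[key] = float(cfg[key])

        def const(v):
            return lambda wl, v=float(v): np.full_like(np.asarray(wl, float), v)

        if "n_wall" in cfg:
            kwargs["n_wall"] = const(cfg["n_wall"])
        elif "wall_material" in cfg:
            if materials is None:
                raise ParameterError("wall_material given but no material library")
            kwargs["n_wall"] = lambda wl: materials.refractive_index(
                cfg["wall_material"], wl
            )
        if "n_medium" in cfg:
            kwargs["n_medium"] = const(cfg["n_medium"])
        elif "medium_material" in cfg:
            if materials is None:
                raise ParameterError("medium_material given but no material library")
            kwargs["n_medium"] = lambda wl: materials.refractive_index(
                cfg["medium_material"], wl
            )
        if "mu_a_wall_per_cm" in cfg:
            kwargs["mu_a_wall"] = const(cfg["mu_a_wall_per_cm"])
        return cls(**kwargs)


def _fresnel_R(n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    return ((n1 - n2) / (n1 + n2)) ** 2


def _stack(elements) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compose (T, R_front, R_back) triples of layers/interfaces in order.

    Two-beam incoherent composition: T = T1 T2 / D, Rf = Rf1 + T1^2 Rf2 / D,
    Rb = Rb2 + T2^2 Rb1 / D with D = 1 - Rb1 Rf2.
    """
    T, Rf, Rb = elements[0]
    for T2, Rf2, Rb2 in elements[1:]:
        D = 1.0 - Rb * Rf2
        T, Rf, Rb = (
            T * T2 / D,
            Rf + T**2 * Rf2 / D,
            Rb2 + T2**2 * Rb / D,
        )
    return T, Rf, Rb


def _stack_transmittance(
    wl: np.ndarray,
    mu_a_medium: np.ndarray,
    geom: CuvetteGeometry,
    mu_a_wall: Optional[np.ndarray] = None,
) -> np.ndarray:
    n_a = np.full(wl.shape, float(geom.n_ambient))
    n_w = np.asarray(geom.n_wall(wl), dtype=float)
    n_m = np.asarray(geom.n_medium(wl), dtype=float)
    mu_w = (
        np.asarray(geom.mu_a_wall(wl), dtype=float)
        if mu_a_wall is None
        else np.asarray(mu_a_wall, dtype=float)
    )
    t_wall = np.exp(-mu_w * geom.wall_thickness_cm)
    t_med = np.exp(-np.asarray(mu_a_medium, float) * geom.inner_path_cm)

    R_aw = _fresnel_R(n_a, n_w)
    R_wm = _fresnel_R(n_w, n_m)
    elements = [
        (1.0 - R_aw, R_aw, R_aw),
        (t_wall, np.zeros_like(t_wall), np.zeros_like(t_wall)),
        (1.0 - R_wm, R_wm, R_wm),
        (t_med, np.zeros_like(t_med), np.zeros_like(t_med)),
        (1.0 - R_wm, R_wm, R_wm),
        (t_wall, np.zeros_like(t_wall), np.zeros_like(t_wall)),
        (1.0 - R_aw, R_aw, R_aw),
    ]
    T, _, _ = _stack(elements)
    return T


def cuvette_transmittance(mu_a_medium: Spectrum, geom: CuvetteGeometry) -> Spectrum:
    """Collimated transmittance of the filled cuvette at each wavelength."""
    if mu_a_medium.kind != "mu_a":
        raise ParameterError(f"expected a mu_a spectrum, got kind {mu_a_medium.kind!r}")
    if np.any(mu_a_medium.values < 0):
        raise ParameterError("mu_a must be non-negative")
    T = _stack_transmittance(mu_a_medium.wavelengths, mu_a_medium.values, geom)
    return Spectrum(mu_a_medium.grid, np.clip(T, 0.0, 1.0), kind="transmittance")


def extract_mu_a(
    T_measured: Spectrum,
    geom: CuvetteGeometry,
    mu_a_max: float = 1.0e3,
    tol_T: float = 1.0e-10,
) -> Spectrum:
    """Invert the forward model for the medium mu_a(lambda), per wavelength.

    Wavelengths where the measured transmittance exceeds the zero-absorption
    prediction are clamped to mu_a = 0 with a warning.
    """
    if T_measured.kind != "transmittance":
        raise ParameterError("expected a transmittance spectrum")
    wl = T_measured.wavelengths
    T = T_measured.values
    if np.any(T <= 0):
        raise ParameterError("transmittance must be positive for inversion")
    out = np.zeros_like(T)
    clamped = []
    for i in range(wl.size):
        w = wl[i : i + 1]

        def f(mu: float) -> float:
            return float(_stack_transmittance(w, np.array([mu]), geom)[0]) - T[i]

        if f(0.0) <= 0.0:  # measurement above the lossless prediction
            clamped.append(float(wl[i]))
            out[i] = 0.0
            continue
        if f(mu_a_max) > 0.0:
            raise ParameterError(
                f"mu_a exceeds the bracket maximum {mu_a_max} cm^-1 at {wl[i]:.1f} nm"
            )
        out[i] = brentq(f, 0.0, mu_a_max, xtol=1e-14, rtol=1e-15, maxiter=200)
        # polish bracket result to the requested transmittance tolerance
        if abs(f(out[i])) > tol_T:
            out[i] = brentq(f, max(out[i] - 1e-6, 0.0), min(out[i] + 1e-6, mu_a_max))
    if clamped:
        warnings.warn(
            f"transmittance above lossless model at {len(clamped)} wavelength(s) "
            f"(first: {clamped[0]:.1f} nm); mu_a clamped to 0",
            stacklevel=2,
        )
    return Spectrum(T_measured.grid, out, kind="mu_a")


def empty_cuvette_wall_mu_a(
    T_empty: Spectrum,
    geom: CuvetteGeometry,
    mu_a_max: float = 1.0e3,
) -> Spectrum:
    """Calibrate wall absorption from an air-filled cuvette (unit content T).

    Solves the same stack with medium = air for the per-wall mu_a, split
    equally between the two walls.
    """
    if T_empty.kind != "transmittance":
        raise ParameterError("expected a transmittance spectrum")
    wl = T_empty.wavelengths
    T = T_empty.values
    if np.any(T <= 0) or np.any(T > 1):
        raise ParameterError("empty-cuvette transmittance must lie in (0, 1]")
    air_geom = CuvetteGeometry(
        inner_path_cm=geom.inner_path_cm,
        wall_thickness_cm=geom.wall_thickness_cm,
        n_wall=geom.n_wall,
        n_medium=lambda w: np.ones_like(np.asarray(w, float)),
        mu_a_wall=geom.mu_a_wall,
        n_ambient=geom.n_ambient,
    )
    out = np.zeros_like(T)
    zeros = np.zeros(1)
    for i in range(wl.size):
        w = wl[i : i + 1]

        def f(mu_wall: float) -> float:
            return (
                float(
                    _stack_transmittance(
                        w, zeros, air_geom, mu_a_wall=np.array([mu_wall])
                    )[0]
                )
                - T[i]
            )

        if f(0.0) <= 0.0:
            out[i] = 0.0
            continue
        if f(mu_a_max) > 0.0:
            raise ParameterError(
                f"wall mu_a exceeds bracket maximum {mu_a_max} cm^-1 at {wl[i]:.1f} nm"
            )
        out[i] = brentq(f, 0.0, mu_a_max, xtol=1e-14, rtol=1e-15, maxiter=200)
    return Spectrum(T_empty.grid, out, kind="mu_a")


def scale_mu_a(mu_a: Spectrum, fraction_from: float, fraction_to: float) -> Spectrum:
    """Linear rescaling of an absorber spectrum between dilution fractions.

    The pigment absorption is proportional to its fraction in the mix, so
    mu_a at ``fraction_to`` = mu_a * fraction_to / fraction_from.
    """
    if fraction_from <= 0 or fraction_to < 0:
        raise ParameterError("fractions must be positive (from) / non-negative (to)")
    return Spectrum(
        mu_a.grid, mu_a.values * (fraction_to / fraction_from), kind=mu_a.kind
    )
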