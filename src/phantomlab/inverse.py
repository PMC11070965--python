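"""Inverse problem: recover constituent fractions from a reflectance spectrum.

The phantom forward model composes per-wavelength optical properties from two
free parameters — the scatterer volume fraction f_scat and the diluted-pigment
fraction f_pig:

    mu_a(l) = f_pig * mu_a_pigment(l) + (1 - f_pig - f_scat) * mu_a_host(l)
    mu_s(l) = f_scat * mu_s_unit(l)        (unit-volume-fraction mixture)
    g(l), n(l): composition-independent (mixture anisotropy, host index)

and pushes them through the photon Monte Carlo to a diffuse reflectance
spectrum.  The fit is bound-constrained nonlinear least squares on the
reflectance residuals, evaluated under common random numbers so the
stochastic forward model becomes a deterministic objective.

Goodness-of-fit mirrors the usual reporting for this kind of phantom work:
global RMSE plus mean and max |Delta R| inside wavelength windows (default
420-850 and 850-980 nm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, GridMismatchError, ParameterError
from .materials import MaterialLibrary
from .mixture import (
    OpticalProperties,
    PhantomComposition,
    WallThicknessModel,
    mixture_optical_props,
    volume_to_mass_fraction,
)
from .sizing import SizeDistribution
from .spectra import Spectrum, SpectralGrid, resample
from .transport import spectral_path_sets, spectral_reflectance

log = logging.getLogger(__name__)

#: default fit grid: 166 wavelengths spanning 420-980 nm
DEFAULT_FIT_GRID = SpectralGrid.uniform(420.0, 980.0, 166)
DEFAULT_WINDOWS: Tuple[Tuple[float, float], ...] = ((420.0, 850.0), (850.0, 980.0))


@dataclass(frozen=True)
class FitConfig:
    """Settings of the inverse solve; defaults give the full-scale fit."""

    grid: SpectralGrid = field(default_factory=lambda: DEFAULT_FIT_GRID)
    n_photons: int = 20_000
    seed: int = 0
    init: Tuple[float, float] = (0.05, 0.10)  # (f_scat, f_pig)
    diff_step: float = 1.0e-3
    xtol: float = 1.0e-6
    max_nfev: int = 60
    multi_start: bool = False
    include_specular: bool = False
    ambient_n: float = 1.0
    g_weighting: str = "literal"
    windows: Tuple[Tuple[float, float], ...] = DEFAULT_WINDOWS


@dataclass(frozen=True)
class FitResult:
    """Recovered composition with goodness-of-fit metrics."""

    composition: PhantomComposition
    rmse: float
    window_metrics: Dict[Tuple[float, float], Tuple[float, float]]
    n_iterations: int
    converged: bool
    seed: int
    model_reflectance: Optional[Spectrum] = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ParameterError("rmse must be non-negative")


class PhantomForwardModel:
    """Caches the composition-independent pieces of the forward model.

    The mixture mu_s at unit volume fraction, the mixture anisotropy, the
    pigment/host absorption curves and the host index depend only on the
    fixed inputs, so they are computed once; each objective evaluation is
    then two array operations plus the Monte Carlo.
    """

    def __init__(
        self,
        dist: SizeDistribution,
        wall: WallThicknessModel,
        materials: MaterialLibrary,
        grid: SpectralGrid,
        g_weighting: str = "literal",
    ):
        if "pigment" not in materials:
            raise ConfigurationError("materials must provide the pigment absorber")
        self.grid = grid
        mu_s_unit, g_spec = mixture_optical_props(
            dist, wall, materials, grid, volume_fraction=1.0, g_weighting=g_weighting
        )
        self.mu_s_unit = mu_s_unit.values
        self.g = g_spec.values
        wl = grid.wavelengths
        self.mu_a_pigment = materials.absorption("pigment", wl)
        self.mu_a_host = materials.absorption("siliglass", wl)
        self.n_host = materials.refractive_index("siliglass", wl)
        self._path_cache: dict = {}

    def optical_properties(self, f_scat: float, f_pig: float) -> OpticalProperties:
        host_frac = max(1.0 - f_scat - f_pig, 0.0)
        mu_a = f_pig * self.mu_a_pigment + host_frac * self.mu_a_host
        return OpticalProperties(
            self.grid,
            mu_a=mu_a,
            mu_s=f_scat * self.mu_s_unit,
            g=self.g,
            n=self.n_host,
        )

    def reflectance(
        self,
        f_scat: float,
        f_pig: float,
        n_photons: int,
        seed: int,
        ambient_n: float = 1.0,
        include_specular: bool = False,
    ) -> Spectrum:
        # the scattering-only path sets depend only on (g, n, photons, seed),
        # so they are traced once and reused across compositions — this is
        # both the common-random-numbers scheme and the dominant cost saving
        key = (int(n_photons), int(seed), float(ambient_n))
        paths = self._path_cache.get(key)
        if paths is None:
            paths = spectral_path_sets(
                self.g, self.n_host, ambient_n, n_photons, seed
            )
            self._path_cache[key] = paths
        return spectral_reflectance(
            self.optical_properties(f_scat, f_pig),
            ambient_n=ambient_n,
            n_photons=n_photons,
            seed=seed,
            include_specular=include_specular,
            path_sets=paths,
        )


def compose_properties(
    comp: PhantomComposition,
    dist: SizeDistribution,
    wall: WallThicknessModel,
    materials: MaterialLibrary,
    grid: SpectralGrid,
    g_weighting: str = "literal",
) -> OpticalProperties:
    """Optical properties of a phantom with the given composition."""
    model = PhantomForwardModel(dist, wall, materials, grid, g_weighting)
    return model.optical_properties(
        comp.scatterer_volume_fraction, comp.pigment_fraction
    )


def goodness_of_fit(
    R_measured: Spectrum,
    R_model: Spectrum,
    windows: Sequence[Tuple[float, float]] = DEFAULT_WINDOWS,
) -> Dict[str, object]:
    """RMSE over the full grid plus per-window (mean |dR|, max |dR|).

    Window membership is lo <= lambda < hi; the last window includes its
    right edge.
    """
    if R_measured.grid != R_model.grid:
        raise GridMismatchError("measured and model spectra on different grids")
    wl = R_measured.wavelengths
    dr = R_measured.values - R_model.values
    out: Dict[str, object] = {"rmse": float(np.sqrt(np.mean(dr**2)))}
    win_metrics: Dict[Tuple[float, float], Tuple[float, float]] = {}
    for k, (lo, hi) in enumerate(windows):
        last = k == len(windows) - 1
        sel = (wl >= lo) & ((wl <= hi) if last else (wl < hi))
        if np.any(sel):
            win_metrics[(lo, hi)] = (
                float(np.mean(np.abs(dr[sel]))),
                float(np.max(np.abs(dr[sel]))),
            )
        else:
            win_metrics[(lo, hi)] = (0.0, 0.0)
    out["windows"] = win_metrics
    return out


def fit_composition(
    R_measured: Spectrum,
    dist: SizeDistribution,
    wall: WallThicknessModel,
    materials: MaterialLibrary,
    config: FitConfig = FitConfig(),
    model: Optional[PhantomForwardModel] = None,
) -> FitResult:
    """Bound-constrained least-squares fit of (f_scat, f_pig) to a spectrum.

    The measured spectrum is resampled onto the fit grid.  Every objective
    evaluation reuses the same Monte Carlo substream seeds (common random
    numbers), so the trust-region-reflective optimizer sees a deterministic,
    finite-difference-friendly objective.  Pass a prebuilt ``model`` to skip
    the Mie mixture precomputation (useful for repeated fits).
    """
    if model is None:
        model = PhantomForwardModel(
            dist, wall, materials, config.grid, config.g_weighting
        )
    elif model.grid != config.grid:
        raise GridMismatchError("prebuilt model grid differs from config grid")
    meas = resample(R_measured, config.grid)

    def residuals(x: np.ndarray) -> np.ndarray:
        r_mod = model.reflectance(
            x[0],
            x[1],
            config.n_photons,
            config.seed,
            config.ambient_n,
            config.include_specular,
        )
        res = r_mod.values - meas.values
        log.debug(
            "fit eval f_scat=%.6f f_pig=%.6f loss=%.3e", x[0], x[1], float(res @ res)
        )
        if not np.all(np.isfinite(res)):
            raise ParameterError(
                f"non-finite residuals at f_scat={x[0]:.4g}, f_pig={x[1]:.4g}"
            )
        return res

    inits = [np.asarray(config.init, dtype=float)]
    if config.multi_start:
        inits = [
            np.array([fs, fp])
            for fs in (0.01, 0.05, 0.10)
            for fp in (0.05, 0.20, 0.40)
        ]

    best = None
    total_nfev = 0
    for x0 in inits:
        sol = least_squares(
            residuals,
            x0,
            bounds=([0.0, 0.0], [1.0, 1.0]),
            method="trf",
            diff_step=config.diff_step,
            xtol=config.xtol,
            max_nfev=config.max_nfev,
        )
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    assert best is not None
    f_scat, f_pig = float(best.x[0]), float(best.x[1])
    r_best = model.reflectance(
        f_scat,
        f_pig,
        config.n_photons,
        config.seed,
        config.ambient_n,
        config.include_specular,
    )
    gof = goodness_of_fit(meas, r_best, config.windows)
    return FitResult(
        composition=PhantomComposition(
            scatterer_volume_fraction=min(f_scat, 1.0 - f_pig), pigment_fraction=f_pig
        ),
        rmse=gof["rmse"],  # type: ignore[arg-type]
        window_metrics=gof["windows"],  # type: ignore[arg-type]
        n_iterations=total_nfev,
        converged=bool(best.status > 0),
        seed=config.seed,
        model_reflectance=r_best,
    )


def fractions_report(
    fit: FitResult, density_ratio: float = 1.196
) -> Dict[str, float]:
    """Side-by-side volume and mass fractions of the fitted composition.

    The scatterer volume fraction converts to a mass fraction through the
    two-component density formula (rho_scatterer/rho_host = ``density_ratio``).
    The pigment term is a fraction of the diluted stock whose density is
    taken equal to the host, so its mass and volume fractions coincide.
    """
    v_scat = fit.composition.scatterer_volume_fraction
    f_pig = fit.composition.pigment_fraction
    return {
        "scatterer_volume_fraction": v_scat,
        "scatterer_mass_fraction": volume_to_mass_fraction(v_scat, density_ratio),
        "pigment_fraction": f_pig,
        "pigment_mass_fraction": f_pig,
        "density_ratio": density_ratio,
        "rmse": fit.rmse,
    }
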