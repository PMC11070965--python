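"""Spectral data model shared by every stage of the pipeline.

Wavelengths are always nanometres, absorption/scattering coefficients cm^-1,
particle geometry micrometres.  ``SpectralGrid`` carries the wavelength axis,
``Spectrum`` a scalar series on that axis, ``HyperCube`` a spatial stack of
spectra (rows x cols x wavelengths).  Reflectance/transmittance normalization
against white-reference measurements and the RGB projection used for visual
inspection live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .errors import (
    DivisionGuardError,
    GridMismatchError,
    ParameterError,
    SpectralRangeError,
)

#: conversion constants, centralized: geometry in um, coefficients per cm
UM_PER_CM = 1.0e4
NM_PER_UM = 1.0e3

#: tolerated overshoot above 1 for normalized reflectance/transmittance
DEFAULT_OVERSHOOT_TOL = 0.05

_KINDS = frozenset(
    {
        "intensity",
        "reflectance",
        "transmittance",
        "mu_a",
        "mu_s",
        "anisotropy",
        "refractive_index",
    }
)


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength axis in nm, restricted to 200-2000 nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ParameterError("grid needs at least two wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if wl[0] < 200.0 or wl[-1] > 2000.0:
            raise ParameterError("wavelengths must lie within [200, 2000] nm")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    @classmethod
    def uniform(cls, lo_nm: float, hi_nm: float, n: int) -> "SpectralGrid":
        return cls(np.linspace(lo_nm, hi_nm, n))


def _validate_values(values: np.ndarray, kind: str, overshoot_tol: float) -> None:
    if kind not in _KINDS:
        raise ParameterError(f"unknown spectrum kind {kind!r}; one of {sorted(_KINDS)}")
    if not np.all(np.isfinite(values)):
        raise ParameterError("spectrum values must be finite")
    if kind in ("reflectance", "transmittance"):
        if np.any(values < 0) or np.any(values > 1.0 + overshoot_tol):
            raise ParameterError(
                f"{kind} must lie in [0, 1+{overshoot_tol}]; "
                f"range is [{values.min():.4g}, {values.max():.4g}]"
            )
    elif kind in ("mu_a", "mu_s", "intensity"):
        if np.any(values < 0):
            raise ParameterError(f"{kind} must be non-negative")
    elif kind == "anisotropy":
        if np.any(np.abs(values) > 1):
            raise ParameterError("anisotropy must lie in [-1, 1]")
    elif kind == "refractive_index":
        if np.any(values < 1):
            raise ParameterError("refractive index must be >= 1 for these materials")


@dataclass(frozen=True)
class Spectrum:
    """Scalar series on a :class:`SpectralGrid` with a physical ``kind``."""

    grid: SpectralGrid
    values: np.ndarray
    kind: str = "intensity"
    overshoot_tol: float = DEFAULT_OVERSHOOT_TOL

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != self.grid.wavelengths.shape:
            raise GridMismatchError(
                f"values length {vals.shape} != grid length {len(self.grid)}"
            )
        _validate_values(vals, self.kind, self.overshoot_tol)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def at(self, wavelength_nm: float) -> float:
        """Linear interpolation at one wavelength (must be inside the span)."""
        lo, hi = self.grid.span
        if not (lo <= wavelength_nm <= hi):
            raise SpectralRangeError(
                f"{wavelength_nm} nm outside span [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength_nm, self.wavelengths, self.values))


@dataclass(frozen=True)
class HyperCube:
    """Spatial stack of spectra with shape (rows, cols, n_wavelengths)."""

    grid: SpectralGrid
    data: np.ndarray
    kind: str = "intensity"
    overshoot_tol: float = DEFAULT_OVERSHOOT_TOL

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ParameterError("cube data must be 3-D (rows, cols, wavelengths)")
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ParameterError("cube spatial dimensions must be >= 1")
        if data.shape[2] != len(self.grid):
            raise GridMismatchError(
                f"cube has {data.shape[2]} bands but grid has {len(self.grid)}"
            )
        _validate_values(data, self.kind, self.overshoot_tol)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _check_same_layout(a: HyperCube, b: HyperCube, what: str) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(f"{what}: wavelength grids differ")
    if a.data.shape != b.data.shape:
        raise GridMismatchError(
            f"{what}: spatial shapes differ ({a.data.shape} vs {b.data.shape})"
        )


def normalize_reflectance(
    meas: HyperCube, ref: HyperCube, overshoot_tol: float = DEFAULT_OVERSHOOT_TOL
) -> HyperCube:
    """White-reference normalization R = I_meas / I_ref, element-wise.

    The camera is assumed to have compensated dark current already, so no dark
    frame enters.  Any non-positive reference value is a hard error naming the
    first offending pixel/band.
    """
    _check_same_layout(meas, ref, "normalize_reflectance")
    bad = ref.data <= 0
    if np.any(bad):
        r, c, b = (int(i[0]) for i in np.nonzero(bad))
        raise DivisionGuardError(
            f"reference intensity <= 0 at pixel ({r}, {c}), "
            f"wavelength {ref.grid.wavelengths[b]:.1f} nm"
        )
    out = np.clip(meas.data / ref.data, 0.0, 1.0 + overshoot_tol)
    return HyperCube(meas.grid, out, kind="reflectance", overshoot_tol=overshoot_tol)


def normalize_transmittance(
    meas: HyperCube,
    ref: HyperCube,
    dark: HyperCube,
    overshoot_tol: float = DEFAULT_OVERSHOOT_TOL,
) -> HyperCube:
    """Dark-corrected normalization T = (I_meas - I_dark) / (I_ref - I_dark)."""
    _check_same_layout(meas, ref, "normalize_transmittance")
    _check_same_layout(meas, dark, "normalize_transmittance")
    denom = ref.data - dark.data
    bad = denom <= 0
    if np.any(bad):
        r, c, b = (int(i[0]) for i in np.nonzero(bad))
        raise DivisionGuardError(
            f"(reference - dark) <= 0 at pixel ({r}, {c}), "
            f"wavelength {ref.grid.wavelengths[b]:.1f} nm"
        )
    out = np.clip((meas.data - dark.data) / denom, 0.0, 1.0 + overshoot_tol)
    return HyperCube(meas.grid, out, kind="transmittance", overshoot_tol=overshoot_tol)


def resample(spec: Spectrum, target: SpectralGrid) -> Spectrum:
    """Linear interpolation of a spectrum onto a new grid (no extrapolation)."""
    lo, hi = spec.grid.span
    t = target.wavelengths
    outside = t[(t < lo) | (t > hi)]
    if outside.size:
        raise SpectralRangeError(
            f"target wavelengths outside source span [{lo}, {hi}] nm: "
            f"{np.array2string(outside[:8], precision=2)}"
        )
    vals = np.interp(t, spec.wavelengths, spec.values)
    return Spectrum(target, vals, kind=spec.kind, overshoot_tol=spec.overshoot_tol)


def project_rgb(cube: HyperCube) -> np.ndarray:
    """Project a reflectance/transmittance cube to sRGB for visual inspection.

    Per pixel: integrate the spectrum against the CIE 1931 2-degree observer
    under illuminant D65, normalize by the white point, convert XYZ -> linear
    sRGB -> gamma-encoded sRGB, clip to [0, 1].
    """
    from ._cie import cmf_xyz, d65_spd

    wl = cube.grid.wavelengths
    in_range = (wl >= 380.0) & (wl <= 780.0)
    if not np.any(in_range):
        raise SpectralRangeError(
            "cube grid does not overlap the 380-780 nm CIE observer range"
        )
    wl = wl[in_range]
    spectra = cube.data[:, :, in_range]
    xyz_bar = cmf_xyz(wl)  # (n, 3)
    illum = d65_spd(wl)  # (n,)
    weights = xyz_bar * illum[:, None]  # (n, 3)
    # trapezoidal quadrature on a possibly non-uniform grid
    if wl.size > 1:
        dw = np.gradient(wl)
    else:
        dw = np.ones(1)
    w = weights * dw[:, None]
    norm = w[:, 1].sum()  # white point: flat unit spectrum maps to Y = 1
    xyz = np.tensordot(spectra, w, axes=([2], [0])) / norm
    m = np.array(
        [
            [3.2406, -1.5372, -0.4986],
            [-0.9689, 1.8758, 0.0415],
            [0.0557, -0.2040, 1.0570],
        ]
    )
    rgb_lin = np.clip(xyz @ m.T, 0.0, None)
    srgb = np.where(
        rgb_lin <= 0.0031308,
        12.92 * rgb_lin,
        1.055 * np.power(rgb_lin, 1 / 2.4) - 0.055,
    )
    return np.clip(srgb, 0.0, 1.0)
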