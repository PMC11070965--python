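"""Constituent material properties: refractive index n(lambda) and absorption mu_a(lambda).

Shipped defaults cover the phantom system studied here: a silicone elastomer
host ("siliglass"), fused-silica microsphere shells ("silica"), air cores
("air"), a black silicone pigment dilution ("pigment"), and polystyrene
cuvette walls ("polystyrene").

Fused silica uses the Malitson (1965) Sellmeier equation; polystyrene a
standard Cauchy fit.  The silicone host index and the pigment / host
absorption curves are smooth synthetic stand-ins at realistic magnitudes:
the pigment curve is normalized so that a 33% stock fraction gives
mu_a(600 nm) = 0.99 cm^-1, and host absorption is a few 1e-2 cm^-1.  All of
them can be overridden from a CSV table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SpectralRangeError

Curve = Callable[[np.ndarray], np.ndarray]


def _sellmeier_fused_silica(wl_nm: np.ndarray) -> np.ndarray:
    lam2 = (np.asarray(wl_nm, dtype=float) / 1000.0) ** 2  # um^2
    n2 = (
        1.0
        + 0.6961663 * lam2 / (lam2 - 0.0684043**2)
        + 0.4079426 * lam2 / (lam2 - 0.1162414**2)
        + 0.8974794 * lam2 / (lam2 - 9.896161**2)
    )
    return np.sqrt(n2)


def _cauchy_polystyrene(wl_nm: np.ndarray) -> np.ndarray:
    lam = np.asarray(wl_nm, dtype=float) / 1000.0  # um
    return 1.5725 + 0.0031080 / lam**2 + 0.00034779 / lam**4


def _siliglass_index(wl_nm: np.ndarray) -> np.ndarray:
    # mild normal dispersion around n ~ 1.41, typical of cured silicone rubbers
    wl = np.asarray(wl_nm, dtype=float)
    return 1.404 + 3.0e3 / wl**2


def _pigment_mu_a_unit(wl_nm: np.ndarray) -> np.ndarray:
    # synthetic: smooth, decreasing with wavelength; 0.33 * value(600) = 0.99 cm^-1
    wl = np.asarray(wl_nm, dtype=float)
    return 3.0 * (600.0 / wl) ** 1.8


def _siliglass_mu_a(wl_nm: np.ndarray) -> np.ndarray:
    # synthetic: weak blue absorption tail plus a faint NIR overtone bump
    wl = np.asarray(wl_nm, dtype=float)
    return (
        0.02
        + 0.05 * np.exp(-(wl - 400.0) / 180.0)
        + 0.04 * np.exp(-(((wl - 920.0) / 60.0) ** 2))
    )


@dataclass(frozen=True)
class Material:
    name: str
    n: Optional[Curve] = None
    mu_a: Optional[Curve] = None


class MaterialLibrary:
    """Lookup of n(lambda) [-] and mu_a(lambda) [cm^-1] per constituent."""

    def __init__(self, materials: Dict[str, Material]):
        self._materials = dict(materials)

    def __contains__(self, name: str) -> bool:
        return name in self._materials

    @property
    def names(self) -> list[str]:
        return sorted(self._materials)

    def refractive_index(self, name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        mat = self._get(name)
        if mat.n is None:
            raise ConfigurationError(f"material {name!r} has no refractive index curve")
        return np.asarray(mat.n(np.asarray(wavelengths_nm, dtype=float)), dtype=float)

    def absorption(self, name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        mat = self._get(name)
        if mat.mu_a is None:
            raise ConfigurationError(f"material {name!r} has no absorption curve")
        return np.asarray(mat.mu_a(np.asarray(wavelengths_nm, dtype=float)), dtype=float)

    def with_material(self, material: Material) -> "MaterialLibrary":
        mats = dict(self._materials)
        mats[material.name] = material
        return MaterialLibrary(mats)

    def _get(self, name: str) -> Material:
        try:
            return self._materials[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown material {name!r}; available: {self.names}"
            ) from None

    @classmethod
    def default(cls) -> "MaterialLibrary":
        return cls(
            {
                "siliglass": Material("siliglass", _siliglass_index, _siliglass_mu_a),
                "silica": Material("silica", _sellmeier_fused_silica),
                "air": Material("air", lambda wl: np.ones_like(np.asarray(wl, float))),
                "pigment": Material("pigment", None, _pigment_mu_a_unit),
                "polystyrene": Material("polystyrene", _cauchy_polystyrene),
            }
        )

    @classmethod
    def from_csv(cls, path, base: Optional["MaterialLibrary"] = None) -> "MaterialLibrary":
        """Load/override materials from a table `material,wavelength_nm,n[,mu_a_per_cm]`.

        Tabulated curves are linearly interpolated; queries outside the
        tabulated span raise :class:`SpectralRangeError`.
        """
        df = pd.read_csv(path)
        required = {"material", "wavelength_nm"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"materials CSV needs columns {sorted(required)}, got {list(df.columns)}"
            )
        mats = dict(base._materials) if base is not None else {}
        for name, sub in df.groupby("material"):
            sub = sub.sort_values("wavelength_nm")
            wl = sub["wavelength_nm"].to_numpy(dtype=float)
            n_curve = None
            mu_curve = None
            if "n" in sub.columns and sub["n"].notna().all():
                n_curve = _tabulated(wl, sub["n"].to_numpy(dtype=float), name, "n")
            if "mu_a_per_cm" in sub.columns and sub["mu_a_per_cm"].notna().all():
                mu_curve = _tabulated(
                    wl, sub["mu_a_per_cm"].to_numpy(dtype=float), name, "mu_a"
                )
            mats[str(name)] = Material(str(name), n_curve, mu_curve)
        return cls(mats)


def _tabulated(wl: np.ndarray, vals: np.ndarray, name: str, what: str) -> Curve:
    lo, hi = wl[0], wl[-1]

    def curve(query: np.ndarray) -> np.ndarray:
        q = np.asarray(query, dtype=float)
        if np.any(q < lo) or np.any(q > hi):
            raise SpectralRangeError(
                f"{what} of {name!r} tabulated on [{lo}, {hi}] nm only"
            )
        return np.interp(q, wl, vals)

    return curve
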