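"""Synthetic-data generators emulating every measured input of the study.

Each generator is a pure function of (parameters, seed) and returns the
artifact together with a serializable :class:`SynthTruth` record of the
ground truth, so downstream stages can be validated end-to-end without any
instrument data:

* an analytic bimodal log-normal diameter distribution standing in for the
  SEM-derived microsphere sizing (volume-weighted mean ~13.5 um, sd ~6 um);
* micrograph-style images of anti-aliased bright disks on a dark background;
* cuvette transmittance spectra from a known mu_a(lambda);
* diffuse-reflectance spectra of semi-infinite two-component phantoms with
  known volume fractions plus multiplicative noise (the white-standard
  normalization makes measurement noise multiplicative to first order).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .absorption import CuvetteGeometry, cuvette_transmittance
from .errors import DensityError, ParameterError
from .inverse import PhantomForwardModel
from .materials import MaterialLibrary
from .mixture import PhantomComposition, WallThicknessModel
from .sizing import SizeDistribution
from .spectra import Spectrum, SpectralGrid

#: bimodal log-normal number-fraction mixture; medians in um.
#: Chosen so the volume-weighted distribution has mean ~13.5 um, sd ~6 um
#: (two distinct peaks: many small spheres, few large ones carrying volume).
DEFAULT_SIZE_PARAMS: Dict[str, float] = {
    "median1_um": 3.0,
    "sigma1": 0.45,
    "weight1": 0.82,
    "median2_um": 10.0,
    "sigma2": 0.34,
}


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth of one synthetic artifact; reconstructable from (params, seed)."""

    generator: str
    params: Dict
    seed: Optional[int]
    truth: Dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


def synth_size_distribution(
    params: Optional[Dict[str, float]] = None,
    step_um: float = 0.1,
    span_um: Tuple[float, float] = (0.5, 60.0),
) -> SizeDistribution:
    """Analytic (not sampled) bimodal log-normal diameter distribution.

    The mixture density is evaluated on a uniform ``step_um`` grid and
    binned-normalized; no randomness is involved.
    """
    p = dict(DEFAULT_SIZE_PARAMS)
    if params:
        p.update(params)
    w1 = p["weight1"]
    if not (0 < w1 <= 1):
        raise ParameterError("weight1 must lie in (0, 1]")
    if p["sigma1"] <= 0 or p["sigma2"] <= 0:
        raise ParameterError("sigmas must be positive")
    if p["median1_um"] <= 0 or p["median2_um"] <= 0:
        raise ParameterError("medians must be positive")
    d = np.arange(span_um[0], span_um[1] + step_um / 2, step_um)

    def lognorm_pdf(x, median, sigma):
        return np.exp(-0.5 * ((np.log(x) - np.log(median)) / sigma) ** 2) / (
            x * sigma * np.sqrt(2 * np.pi)
        )

    nf = w1 * lognorm_pdf(d, p["median1_um"], p["sigma1"]) + (1 - w1) * lognorm_pdf(
        d, p["median2_um"], p["sigma2"]
    )
    nf = nf / nf.sum()
    vol = nf * d**3
    return SizeDistribution(d, nf, vol / vol.sum())


def sample_diameters(
    dist: SizeDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw diameters from the binned number-fraction distribution with
    uniform jitter inside each bin."""
    d = dist.diameters_um
    step = np.min(np.diff(d)) if d.size > 1 else 0.1
    idx = rng.choice(d.size, size=n, p=dist.number_fraction)
    return np.clip(d[idx] + rng.uniform(-step / 2, step / 2, size=n), 1e-3, None)


def synth_disk_image(
    dist: SizeDistribution,
    n_disks: int,
    image_size_px: Tuple[int, int] = (1024, 1024),
    scale_um_per_px: float = 0.25,
    noise_sd: float = 0.02,
    seed: int = 0,
    max_attempts: int = 200,
    min_gap_px: float = 3.0,
    background: float = 0.15,
    foreground: float = 0.85,
) -> Tuple[np.ndarray, SynthTruth]:
    """Render non-overlapping anti-aliased bright disks on a dark background.

    Diameters are sampled from ``dist`` (number weighting); placement is
    rejection sampling with ``max_attempts`` tries per disk.  Failure to
    place a disk raises :class:`DensityError`.
    """
    if n_disks < 1:
        raise ParameterError("n_disks must be positive")
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    diams = np.sort(sample_diameters(dist, n_disks, rng))[::-1]  # big first
    radii_px = diams / (2.0 * scale_um_per_px)
    if np.any(radii_px > min(h, w) / 4):
        raise ParameterError("image too small for the largest sampled disk")

    centers = np.empty((n_disks, 2))
    placed_r = np.empty(n_disks)
    for i, r in enumerate(radii_px):
        ok = False
        for _ in range(max_attempts):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if i == 0:
                ok = True
            else:
                dd = np.hypot(
                    centers[:i, 0] - cy, centers[:i, 1] - cx
                )
                ok = bool(np.all(dd > placed_r[:i] + r + min_gap_px))
            if ok:
                centers[i] = (cy, cx)
                placed_r[i] = r
                break
        if not ok:
            raise DensityError(
                f"could not place disk {i + 1}/{n_disks} (r={r:.1f} px) "
                f"after {max_attempts} attempts"
            )

    img = np.full((h, w), background)
    for (cy, cx), r in zip(centers, placed_r):
        y0, y1 = int(max(cy - r - 2, 0)), int(min(cy + r + 3, h))
        x0, x1 = int(max(cx - r - 2, 0)), int(min(cx + r + 3, w))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cover = np.clip(r + 0.5 - np.hypot(yy - cy, xx - cx), 0.0, 1.0)
        img[y0:y1, x0:x1] += (foreground - background) * cover
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = SynthTruth(
        generator="disk_image",
        params={
            "n_disks": n_disks,
            "image_size_px": list(image_size_px),
            "scale_um_per_px": scale_um_per_px,
            "noise_sd": noise_sd,
            "min_gap_px": min_gap_px,
        },
        seed=seed,
        truth={
            "centers_px": centers,
            "radii_px": placed_r,
            "diameters_um": diams,
        },
    )
    return img, truth


def synth_cuvette_dataset(
    mu_a_true: Spectrum,
    geom: CuvetteGeometry,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[Spectrum, SynthTruth]:
    """Cuvette transmittance of a known absorber plus multiplicative noise."""
    T = cuvette_transmittance(mu_a_true, geom)
    vals = T.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + rng.normal(0.0, noise_sd, size=vals.shape))
    vals = np.clip(vals, 1e-12, 1.0)
    truth = SynthTruth(
        generator="cuvette",
        params={"noise_sd": noise_sd},
        seed=seed,
        truth={"mu_a_true": mu_a_true.values, "wavelengths_nm": mu_a_true.wavelengths},
    )
    return Spectrum(mu_a_true.grid, vals, kind="transmittance"), truth


def synth_reflectance_dataset(
    comp_true: PhantomComposition,
    dist: SizeDistribution,
    wall: WallThicknessModel,
    materials: MaterialLibrary,
    grid: SpectralGrid,
    n_photons: int = 20_000,
    noise_sd: float = 0.01,
    seed: int = 0,
    model: Optional[PhantomForwardModel] = None,
    mc_seed: Optional[int] = None,
) -> Tuple[Spectrum, SynthTruth]:
    """Diffuse reflectance of a semi-infinite phantom of known composition.

    ``seed`` drives the measurement noise; the Monte Carlo substreams use
    ``mc_seed`` (default: derived from seed) so synthetic "measurements" are
    statistically independent from any fit that uses a different base seed.
    """
    if model is None:
        model = PhantomForwardModel(dist, wall, materials, grid)
    mc = int(mc_seed) if mc_seed is not None else seed + 77_003
    R = model.reflectance(
        comp_true.scatterer_volume_fraction,
        comp_true.pigment_fraction,
        n_photons,
        mc,
    )
    vals = R.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + rng.normal(0.0, noise_sd, size=vals.shape))
    vals = np.clip(vals, 0.0, 1.0)
    truth = SynthTruth(
        generator="reflectance",
        params={"n_photons": n_photons, "noise_sd": noise_sd, "mc_seed": mc},
        seed=seed,
        truth={
            "scatterer_volume_fraction": comp_true.scatterer_volume_fraction,
            "pigment_fraction": comp_true.pigment_fraction,
        },
    )
    return Spectrum(grid, vals, kind="reflectance"), truth
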