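"""File I/O: spectrum/distribution/circle CSVs and grayscale images.

CSV layouts:
  spectrum        wavelength_nm,value
  optical props   wavelength_nm,mu_a,mu_s,g,n
  distribution    diameter_um,number_fraction,volume_fraction
  circles         row_px,col_px,radius_px,diameter_um
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mixture import OpticalProperties
from .sizing import DetectedCircles, SizeDistribution, pixels_to_um
from .spectra import Spectrum, SpectralGrid

PathLike = Union[str, Path]


def read_spectrum(path: PathLike, kind: str = "intensity") -> Spectrum:
    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"}.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: expected columns wavelength_nm,value; got {list(df.columns)}"
        )
    df = df.sort_values("wavelength_nm")
    grid = SpectralGrid(df["wavelength_nm"].to_numpy(dtype=float))
    return Spectrum(grid, df["value"].to_numpy(dtype=float), kind=kind)


def write_spectrum(spec: Spectrum, path: PathLike) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "value": spec.values}
    ).to_csv(path, index=False)


def read_optical_properties(path: PathLike) -> OpticalProperties:
    df = pd.read_csv(path)
    needed = {"wavelength_nm", "mu_a", "mu_s", "g", "n"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(f"{path}: expected columns {sorted(needed)}")
    df = df.sort_values("wavelength_nm")
    grid = SpectralGrid(df["wavelength_nm"].to_numpy(dtype=float))
    return OpticalProperties(
        grid,
        mu_a=df["mu_a"].to_numpy(dtype=float),
        mu_s=df["mu_s"].to_numpy(dtype=float),
        g=df["g"].to_numpy(dtype=float),
        n=df["n"].to_numpy(dtype=float),
    )


def write_optical_properties(props: OpticalProperties, path: PathLike) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": props.grid.wavelengths,
            "mu_a": props.mu_a,
            "mu_s": props.mu_s,
            "g": props.g,
            "n": props.n,
        }
    ).to_csv(path, index=False)


def read_distribution(path: PathLike) -> SizeDistribution:
    df = pd.read_csv(path)
    needed = {"diameter_um", "number_fraction", "volume_fraction"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(f"{path}: expected columns {sorted(needed)}")
    df = df.sort_values("diameter_um")
    nf = df["number_fraction"].to_numpy(dtype=float)
    vf = df["volume_fraction"].to_numpy(dtype=float)
    return SizeDistribution(
        df["diameter_um"].to_numpy(dtype=float), nf / nf.sum(), vf / vf.sum()
    )


def write_distribution(dist: SizeDistribution, path: PathLike) -> None:
    pd.DataFrame(
        {
            "diameter_um": dist.diameters_um,
            "number_fraction": dist.number_fraction,
            "volume_fraction": dist.volume_fraction,
        }
    ).to_csv(path, index=False)


def write_circles(circles: DetectedCircles, path: PathLike) -> None:
    diam = (
        pixels_to_um(circles)
        if circles.scale_um_per_px is not None
        else np.full(len(circles), np.nan)
    )
    pd.DataFrame(
        {
            "row_px": circles.centers[:, 0],
            "col_px": circles.centers[:, 1],
            "radius_px": circles.radii,
            "diameter_um": diam,
        }
    ).to_csv(path, index=False)


def read_image(path: PathLike) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF/PNG as float in [0, 1]."""
    from skimage import io as skio

    img = skio.imread(path)
    if img.ndim == 3:  # collapse trivial color axes
        img = img.mean(axis=2)
    img = img.astype(float)
    if img.max() > 1.0:
        img /= 65535.0 if img.max() > 255 else 255.0
    return img


def write_image(img: np.ndarray, path: PathLike) -> None:
    from skimage import io as skio

    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    skio.imsave(Path(path), (arr * 65535).astype(np.uint16), check_contrast=False)
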