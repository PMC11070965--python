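"""Minimal ENVI raster reader/writer for hyperspectral cubes.

Supports the subset of the ENVI format this pipeline produces and consumes:
a text ``.hdr`` companion file plus a raw binary cube in BIL, BIP or BSQ
interleave, data types uint8/uint16/float32/float64, band wavelengths in nm.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np

from .errors import ConfigurationError
from .spectra import HyperCube, SpectralGrid

PathLike = Union[str, Path]

_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> Dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise ConfigurationError("not an ENVI header (missing 'ENVI' magic)")
    fields: Dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines()[1:]:
        line = line.strip()
        if not line:
            continue
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lower()
            if val.startswith("{") and "}" not in val:
                buf = val
                continue
            fields[key] = val.strip("{} ")
            key = None
        else:
            buf += " " + line
            if "}" in line:
                fields[key] = buf.strip("{} ")
                key = None
                buf = ""
    return fields


def read_envi(header_path: PathLike, kind: str = "intensity") -> HyperCube:
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise ConfigurationError(f"ENVI header missing field: {exc}") from exc
    if dtype_code not in _DTYPES:
        raise ConfigurationError(f"unsupported ENVI data type {dtype_code}")
    if "wavelength" not in fields:
        raise ConfigurationError("ENVI header lacks band wavelengths")
    wl = np.array([float(s) for s in fields["wavelength"].split(",")])
    if fields.get("wavelength units", "nanometers").lower().startswith("micro"):
        wl = wl * 1e3

    data_path = header_path.with_suffix("")  # strip .hdr
    if not data_path.exists():
        data_path = header_path.with_suffix(".raw")
    if not data_path.exists():
        raise ConfigurationError(f"ENVI data file for {header_path} not found")
    raw = np.fromfile(data_path, dtype=_DTYPES[dtype_code])
    byte_order = int(fields.get("byte order", 0))
    if byte_order == 1:
        raw = raw.byteswap()
    if raw.size != rows * cols * bands:
        raise ConfigurationError(
            f"ENVI data size {raw.size} != lines*samples*bands {rows * cols * bands}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ConfigurationError(f"unsupported interleave {interleave!r}")
    return HyperCube(SpectralGrid(wl), cube.astype(float), kind=kind)


def write_envi(
    cube: HyperCube,
    header_path: PathLike,
    interleave: str = "bsq",
    dtype: type = np.float32,
) -> None:
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ConfigurationError(f"unsupported interleave {interleave!r}")
    dt = np.dtype(dtype)
    if dt not in _DTYPE_CODES:
        raise ConfigurationError(f"unsupported dtype {dt}")
    rows, cols, bands = cube.shape
    data = cube.data.astype(dt)
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    data_path = header_path.with_suffix("")
    out.tofile(data_path)
    wl = ", ".join(f"{w:.3f}" for w in cube.grid.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
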