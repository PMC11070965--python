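"""CIE 1931 2-degree observer and illuminant D65.

The color-matching functions are evaluated from the multi-lobe piecewise
Gaussian analytic fit of Wyman, Sloan & Shirley (JCGT 2013), accurate to about
1% of peak — ample for qualitative RGB projections.  D65 is the standard 10 nm
relative spectral power table (100 at 560 nm), linearly interpolated.
"""

from __future__ import annotations

import numpy as np


def _lobe(wl: np.ndarray, alpha: float, mu: float, s1: float, s2: float) -> np.ndarray:
    sigma = np.where(wl < mu, s1, s2)
    t = (wl - mu) / sigma
    return alpha * np.exp(-0.5 * t * t)


def cmf_xyz(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Return the (n, 3) array of xbar, ybar, zbar at the given wavelengths."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = (
        _lobe(wl, 1.056, 599.8, 37.9, 31.0)
        + _lobe(wl, 0.362, 442.0, 16.0, 26.7)
        - _lobe(wl, 0.065, 501.1, 20.4, 26.2)
    )
    y = _lobe(wl, 0.821, 568.8, 46.9, 40.5) + _lobe(wl, 0.286, 530.9, 16.3, 31.1)
    z = _lobe(wl, 1.217, 437.0, 11.8, 36.0) + _lobe(wl, 0.681, 459.0, 26.0, 13.8)
    return np.stack([x, y, z], axis=-1)


_D65_WL = np.arange(380.0, 781.0, 10.0)
_D65 = np.array(
    [
        49.9755, 54.6482, 82.7549, 91.4860, 93.4318, 86.6823, 104.865, 117.008,
        117.812, 114.861, 115.923, 108.811, 109.354, 107.802, 104.790, 107.689,
        104.405, 104.046, 100.000, 96.3342, 95.7880, 88.6856, 90.0062, 89.5991,
        87.6987, 83.2886, 83.6992, 80.0268, 80.1207, 82.2778, 78.2842, 69.7213,
        71.6091, 74.3490, 61.6040, 69.8856, 75.0870, 63.5927, 46.4182, 66.8054,
        63.3828,
    ]
)


def d65_spd(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Relative spectral power of illuminant D65 (100 at 560 nm)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return np.interp(wl, _D65_WL, _D65)
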