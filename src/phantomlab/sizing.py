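"""Particle sizing: circle detection in micrographs and diameter distributions.

Detection follows the classic recipe for sizing spherical particles in
grayscale micrographs: local contrast enhancement (CLAHE), edge extraction,
and a phase-coded circular Hough transform (Atherton & Kerbyson) in which
each edge pixel votes along its gradient direction for all candidate radii
with a radius-encoding complex phase.  The accumulator magnitude locates
centers; the phase at each peak decodes the radius, which is then refined
against the radial gradient profile.

Distributions are plain histograms: number fractions are normalized counts,
volume fractions weight each bin by the sphere volume (d^3) and renormalize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import exposure
from skimage.feature import canny, peak_local_max

from .errors import ConfigurationError, ParameterError

#: peak threshold scale: a full, thin circle contributes ~2*pi to the
#: (1/r-weighted) accumulator; sensitivity s keeps peaks above (1-s) * this.
_FULL_CIRCLE_RESPONSE = 2.0 * np.pi


@dataclass(frozen=True)
class DetectedCircles:
    """Circle detections in pixel units plus the um-per-pixel scale."""

    centers: np.ndarray  # (n, 2) array of (row, col)
    radii: np.ndarray  # (n,) positive radii in px
    scale_um_per_px: Optional[float] = None
    strengths: Optional[np.ndarray] = None  # accumulator magnitude per circle

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.size == 0:
            centers = centers.reshape(0, 2)
        radii = np.asarray(self.radii, dtype=float).ravel()
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        if centers.shape[0] != radii.shape[0]:
            raise ParameterError("centers and radii length mismatch")
        if np.any(radii <= 0):
            raise ParameterError("radii must be positive")
        if self.scale_um_per_px is not None and self.scale_um_per_px <= 0:
            raise ParameterError("scale must be positive")

    def __len__(self) -> int:
        return int(self.radii.size)


@dataclass(frozen=True)
class SizeDistribution:
    """Binned sphere diameters with number- and volume-fraction weights."""

    diameters_um: np.ndarray
    number_fraction: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_um, dtype=float)
        nf = np.asarray(self.number_fraction, dtype=float)
        vf = np.asarray(self.volume_fraction, dtype=float)
        object.__setattr__(self, "diameters_um", d)
        object.__setattr__(self, "number_fraction", nf)
        object.__setattr__(self, "volume_fraction", vf)
        if not (d.shape == nf.shape == vf.shape):
            raise ParameterError("distribution arrays must share shape")
        if np.any(d <= 0) or not np.all(np.diff(d) > 0):
            raise ParameterError("diameters must be positive and strictly increasing")
        for name, w in (("number_fraction", nf), ("volume_fraction", vf)):
            if np.any(w < 0):
                raise ParameterError(f"{name} must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1 (got {w.sum():.12f})")


def detect_circles(
    image: np.ndarray,
    radius_range: Tuple[float, float],
    sensitivity: float = 0.9,
    scale_um_per_px: Optional[float] = None,
    polarity: str = "bright",
) -> DetectedCircles:
    """Find circular particles of radius within ``radius_range`` (pixels).

    ``sensitivity`` in (0, 1] raises/lowers the accumulator threshold exactly
    like the phase-coded Hough implementations common in image-analysis
    toolboxes: higher values find fainter/more partial circles at the cost of
    false positives.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("image must be 2-D grayscale")
    rmin, rmax = radius_range
    if not (0 < rmin < rmax < min(img.shape) / 2):
        raise ParameterError(
            f"need 0 < rmin < rmax < min(image dims)/2, got {radius_range}"
        )
    if not (0 < sensitivity <= 1):
        raise ParameterError("sensitivity must lie in (0, 1]")
    if polarity not in ("bright", "dark"):
        raise ParameterError("polarity must be 'bright' or 'dark'")

    ptp = img.max() - img.min()
    if ptp == 0:  # constant image: nothing to detect
        return DetectedCircles(np.empty((0, 2)), np.empty(0), scale_um_per_px)
    img = (img - img.min()) / ptp
    img_eq = exposure.equalize_adapthist(img)

    # thin edges + smoothed gradient field for vote directions
    edges = canny(img_eq, sigma=1.5)
    gy, gx = np.gradient(gaussian_filter(img_eq, 1.5))
    ey, ex = np.nonzero(edges)
    if ey.size == 0:
        return DetectedCircles(np.empty((0, 2)), np.empty(0), scale_um_per_px)
    vy = gy[ey, ex]
    vx = gx[ey, ex]
    mag = np.hypot(vy, vx)
    keep = mag > 1e-12
    ey, ex, vy, vx, mag = ey[keep], ex[keep], vy[keep], vx[keep], mag[keep]
    vy /= mag
    vx /= mag
    if polarity == "dark":  # gradient points away from a dark disk's center
        vy, vx = -vy, -vx

    # log-phase-coded radii
    n_r = int(min(max(rmax - rmin + 1, 8), 120))
    radii = np.exp(np.linspace(np.log(rmin), np.log(rmax), n_r))
    log_span = np.log(rmax * 1.02) - np.log(rmin)
    phases = np.exp(2j * np.pi * (np.log(radii) - np.log(rmin)) / log_span)

    acc = np.zeros(img.shape, dtype=complex)
    flat = acc.ravel()
    h, w = img.shape
    for r, ph in zip(radii, phases):
        cy = np.rint(ey + r * vy).astype(np.intp)
        cx = np.rint(ex + r * vx).astype(np.intp)
        ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
        np.add.at(flat, cy[ok] * w + cx[ok], ph / r)

    acc = gaussian_filter(acc.real, 1.0) + 1j * gaussian_filter(acc.imag, 1.0)
    accmag = np.abs(acc)

    thr = (1.0 - sensitivity) * _FULL_CIRCLE_RESPONSE
    peaks = peak_local_max(
        accmag,
        min_distance=max(1, int(round(rmin / 2))),
        threshold_abs=thr,
        exclude_border=False,
    )
    if peaks.size == 0:
        return DetectedCircles(np.empty((0, 2)), np.empty(0), scale_um_per_px)

    # decode radii from accumulator phase, then refine on the gradient profile
    grad_mag = np.hypot(gy, gx)
    edge_grad = float(np.median(grad_mag[ey, ex]))
    cand_r = []
    coverage = []
    for py, px in peaks:
        ang = np.angle(acc[py, px]) % (2 * np.pi)
        r0 = np.exp(np.log(rmin) + ang / (2 * np.pi) * log_span)
        r_ref = _refine_radius(grad_mag, py, px, r0, rmin, rmax)
        cand_r.append(r_ref)
        coverage.append(_ring_coverage(grad_mag, py, px, r_ref, 0.4 * edge_grad))
    cand_r = np.asarray(cand_r)
    coverage = np.asarray(coverage)
    strengths = accmag[peaks[:, 0], peaks[:, 1]]

    # geometric validation: a genuine circle has edge response around most
    # of its perimeter; accumulator strength alone cannot separate faint
    # small circles from chance alignments
    valid = coverage >= 0.6
    peaks, cand_r, strengths = peaks[valid], cand_r[valid], strengths[valid]
    if peaks.size == 0:
        return DetectedCircles(np.empty((0, 2)), np.empty(0), scale_um_per_px)

    keep_idx = _non_max_suppress(peaks.astype(float), cand_r, strengths, rmin)
    return DetectedCircles(
        peaks[keep_idx].astype(float),
        cand_r[keep_idx],
        scale_um_per_px,
        strengths[keep_idx],
    )


def _refine_radius(
    grad_mag: np.ndarray, cy: int, cx: int, r0: float, rmin: float, rmax: float
) -> float:
    """Maximize the mean gradient magnitude on circles around (cy, cx)."""
    lo = max(rmin * 0.8, r0 - max(3.0, 0.25 * r0))
    hi = min(rmax * 1.2, r0 + max(3.0, 0.25 * r0))
    rs = np.arange(lo, hi + 0.25, 0.25)
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    ys = cy + rs[:, None] * np.sin(theta)
    xs = cx + rs[:, None] * np.cos(theta)
    prof = map_coordinates(
        grad_mag, [ys.ravel(), xs.ravel()], order=1, mode="constant"
    ).reshape(rs.size, theta.size).mean(axis=1)
    i = int(np.argmax(prof))
    if 0 < i < rs.size - 1:  # parabolic sub-step interpolation
        denom = prof[i - 1] - 2 * prof[i] + prof[i + 1]
        if denom < 0:
            i_frac = 0.5 * (prof[i - 1] - prof[i + 1]) / denom
            return float(rs[i] + np.clip(i_frac, -1, 1) * 0.25)
    return float(rs[i])


def _ring_coverage(
    grad_mag: np.ndarray, cy: float, cx: float, r: float, thr: float,
    n_angles: int = 48,
) -> float:
    """Fraction of the circle perimeter with edge response in a +-2 px band."""
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    band = np.linspace(r - 2.0, r + 2.0, 5)
    ys = cy + band[:, None] * np.sin(theta)
    xs = cx + band[:, None] * np.cos(theta)
    vals = map_coordinates(
        grad_mag, [ys.ravel(), xs.ravel()], order=1, mode="constant"
    ).reshape(band.size, n_angles)
    return float(np.mean(vals.max(axis=0) >= thr))


def _non_max_suppress(
    centers: np.ndarray, radii: np.ndarray, strengths: np.ndarray, rmin: float
) -> np.ndarray:
    """Greedy suppression: drop detections whose center falls within the
    stronger detection's footprint (distance < max(rmin, smaller radius))."""
    order = np.argsort(-strengths)
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            dist = np.hypot(*(centers[i] - centers[j]))
            if dist < max(rmin, min(radii[i], radii[j])):
                ok = False
                break
        if ok:
            kept.append(i)
    return np.asarray(sorted(kept), dtype=int)


def pixels_to_um(circles: DetectedCircles) -> np.ndarray:
    """Diameters in um: d_i = 2 * r_i[px] * scale[um/px]."""
    if circles.scale_um_per_px is None:
        raise ConfigurationError("DetectedCircles carries no um-per-pixel scale")
    return 2.0 * circles.radii * circles.scale_um_per_px


def build_distribution(
    diameters_um: Sequence[float], bin_width_um: float = 0.5
) -> SizeDistribution:
    """Histogram diameters; number fractions sum to 1, volume fractions ~ d^3."""
    d = np.asarray(diameters_um, dtype=float).ravel()
    if d.size == 0:
        raise ParameterError("need at least one diameter")
    if np.any(d <= 0):
        raise ParameterError("diameters must be positive")
    if bin_width_um <= 0:
        raise ParameterError("bin width must be positive")
    # bin centers sit on multiples of the bin width so that round diameters
    # (e.g. 10 and 20 um at 1 um bins) land on centers exactly
    c_min = max(int(np.round(d.min() / bin_width_um)), 1)
    c_max = max(int(np.round(d.max() / bin_width_um)), c_min)
    centers = np.arange(c_min, c_max + 1) * bin_width_um
    edges = np.concatenate([centers - bin_width_um / 2, centers[-1:] + bin_width_um / 2])
    edges[0] = min(edges[0], d.min() - 1e-12)  # catch sub-half-bin stragglers
    edges[-1] = max(edges[-1], d.max() + 1e-12)
    counts, _ = np.histogram(d, bins=edges)
    nf = counts / counts.sum()
    vol = nf * centers**3
    vf = vol / vol.sum()
    return SizeDistribution(centers, nf, vf)


def smooth_distribution(dist: SizeDistribution, window: int = 11) -> SizeDistribution:
    """Centered moving average with shrinking edge windows, then renormalize."""
    n = dist.diameters_um.size
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be an odd positive integer")
    if window > n:
        raise ParameterError(f"window {window} exceeds bin count {n}")
    kernel = np.ones(window)
    cover = np.convolve(np.ones(n), kernel, mode="same")

    def avg(w: np.ndarray) -> np.ndarray:
        s = np.convolve(w, kernel, mode="same") / cover
        return s / s.sum()

    return SizeDistribution(
        dist.diameters_um, avg(dist.number_fraction), avg(dist.volume_fraction)
    )


def summarize(dist: SizeDistribution, weighting: str = "volume") -> Tuple[float, float]:
    """Weighted mean and standard deviation of bin-center diameters in um."""
    if weighting == "number":
        w = dist.number_fraction
    elif weighting == "volume":
        w = dist.volume_fraction
    else:
        raise ParameterError("weighting must be 'number' or 'volume'")
    d = dist.diameters_um
    mean = float(np.sum(w * d))
    var = float(np.sum(w * (d - mean) ** 2))
    return mean, float(np.sqrt(max(var, 0.0)))
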