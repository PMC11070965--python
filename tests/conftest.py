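import numpy as np
import pytest

import phantomlab as pl


@pytest.fixture(scope="session")
def materials():
    return pl.MaterialLibrary.default()


@pytest.fixture(scope="session")
def wall_model():
    return pl.WallThicknessModel()


@pytest.fixture(scope="session")
def size_dist():
    return pl.synth_size_distribution()


@pytest.fixture(scope="session")
def fit_grid_20():
    """Reduced 20-wavelength grid on the 420-980 nm fit range."""
    return pl.SpectralGrid.uniform(420.0, 980.0, 20)


@pytest.fixture(scope="session")
def forward_model(size_dist, wall_model, materials, fit_grid_20):
    """Shared phantom forward model on the reduced grid (Mie precompute ~10 s)."""
    return pl.PhantomForwardModel(size_dist, wall_model, materials, fit_grid_20)


def match_circles(det, true_centers, true_radii, tol_px=3.0):
    """Greedy matching of detections to ground truth; returns (tp, fp, fn, radius errors)."""
    used = set()
    tp = 0
    rerr = []
    for c, r in zip(det.centers, det.radii):
        d = np.hypot(true_centers[:, 0] - c[0], true_centers[:, 1] - c[1])
        j = int(np.argmin(d))
        if d[j] <= tol_px and j not in used:
            used.add(j)
            tp += 1
            rerr.append(abs(r - true_radii[j]))
    fp = len(det) - tp
    fn = len(true_radii) - tp
    return tp, fp, fn, np.asarray(rerr)
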