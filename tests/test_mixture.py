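"""Polydisperse mixture model: weighting, scaling, fraction conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phantomlab as pl
from phantomlab.errors import ParameterError
from phantomlab.mixture import interpolate_distribution


def small_dist():
    d = np.array([4.0, 18.0])
    nf = np.array([0.9, 0.1])
    vf = nf * d**3
    return pl.SizeDistribution(d, nf, vf / vf.sum())


def small_grid():
    return pl.SpectralGrid(np.array([500.0, 600.0, 800.0]))


def naive_mixture_oracle(dist, wall, materials, grid, fv, g_weighting="literal"):
    """Explicit triple loop over (wall, diameter, wavelength)."""
    wl = grid.wavelengths
    n_host = materials.refractive_index("siliglass", wl)
    n_shell = materials.refractive_index("silica", wl)
    mu = np.zeros(wl.size)
    gn = np.zeros(wl.size)
    gd = np.zeros(wl.size)
    for t, wt in zip(wall.thicknesses_um, wall.weights):
        for d, phi in zip(dist.diameters_um, dist.volume_fraction):
            r = d / 2
            for k in range(wl.size):
                if r > t:
                    q = pl.mie_coated(
                        pl.SphereSpec(d, t), wl[k], 1.0, n_shell[k], n_host[k]
                    ).Qs
                    g = pl.mie_solid(2 * (r - t), wl[k], 1.0, n_host[k]).g
                else:
                    res = pl.mie_solid(d, wl[k], n_shell[k], n_host[k])
                    q, g = res.Qs, res.g
                m = pl.per_size_mu_s(d, q, 1.0)
                mu[k] += wt * phi * m
                if g_weighting == "literal":
                    gn[k] += wt * phi * g
                    gd[k] += wt * phi
                else:
                    gn[k] += wt * phi * m * g
                    gd[k] += wt * phi * m
    return fv * mu, gn / gd


class TestPerSizeMuS:
    def test_zero_fraction(self):
        assert pl.per_size_mu_s(10.0, 2.0, 0.0) == 0.0

    def test_printed_arithmetic(self):
        # d = 10 um = 1e-3 cm, Qs = 2, f_v = 1%: 0.01 * 3 * 2 / (2 * 1e-3)
        assert pl.per_size_mu_s(10.0, 2.0, 0.01) == pytest.approx(30.0)

    def test_linear_in_fraction(self):
        assert pl.per_size_mu_s(7.0, 1.3, 0.04) == pytest.approx(
            2 * pl.per_size_mu_s(7.0, 1.3, 0.02)
        )

    def test_zero_diameter_rejected(self):
        with pytest.raises(ParameterError):
            pl.per_size_mu_s(0.0, 1.0, 0.1)


class TestMixture:
    @pytest.mark.parametrize("g_weighting", ["literal", "scattering"])
    def test_matches_naive_loop(self, materials, g_weighting):
        dist = small_dist()
        wall = pl.WallThicknessModel(np.array([0.8, 1.0]))
        grid = small_grid()
        mu_s, g = pl.mixture_optical_props(
            dist, wall, materials, grid, 0.05,
            g_weighting=g_weighting, interp_step_um=None,
        )
        mu_ref, g_ref = naive_mixture_oracle(
            dist, wall, materials, grid, 0.05, g_weighting
        )
        np.testing.assert_allclose(mu_s.values, mu_ref, rtol=1e-10)
        np.testing.assert_allclose(g.values, g_ref, rtol=1e-10)

    def test_single_bin_solid_equals_per_size(self, materials):
        # one 1.2 um sphere: radius 0.6 < min wall 0.7 -> solid glass branch
        dist = pl.SizeDistribution(
            np.array([1.2]), np.array([1.0]), np.array([1.0])
        )
        grid = small_grid()
        wall = pl.WallThicknessModel()
        mu_s, g = pl.mixture_optical_props(dist, wall, materials, grid, 0.02)
        wl = grid.wavelengths
        for k in range(wl.size):
            n_host = materials.refractive_index("siliglass", wl[k : k + 1])[0]
            n_shell = materials.refractive_index("silica", wl[k : k + 1])[0]
            res = pl.mie_solid(1.2, wl[k], n_shell, n_host)
            assert mu_s.values[k] == pytest.approx(
                pl.per_size_mu_s(1.2, res.Qs, 0.02), rel=1e-12
            )
            assert g.values[k] == pytest.approx(res.g, rel=1e-12)

    def test_linear_rescaling_in_volume_fraction(self, materials):
        dist = small_dist()
        wall = pl.WallThicknessModel(np.array([0.9]))
        grid = small_grid()
        lo, _ = pl.mixture_optical_props(
            dist, wall, materials, grid, 0.01, interp_step_um=None
        )
        hi, _ = pl.mixture_optical_props(
            dist, wall, materials, grid, 0.10, interp_step_um=None
        )
        np.testing.assert_allclose(hi.values, 10.0 * lo.values, rtol=1e-12)

    def test_mixture_g_within_component_range(self, materials):
        dist = small_dist()
        wall = pl.WallThicknessModel(np.array([0.9]))
        grid = small_grid()
        _, g_mix = pl.mixture_optical_props(
            dist, wall, materials, grid, 0.05, interp_step_um=None
        )
        g_comps = []
        for d in dist.diameters_um:
            sub = pl.SizeDistribution(np.array([d]), np.array([1.0]), np.array([1.0]))
            _, g = pl.mixture_optical_props(
                sub, wall, materials, grid, 0.05, interp_step_um=None
            )
            g_comps.append(g.values)
        g_comps = np.array(g_comps)
        assert np.all(g_mix.values >= g_comps.min(axis=0) - 1e-12)
        assert np.all(g_mix.values <= g_comps.max(axis=0) + 1e-12)

    def test_bin_permutation_invariance(self, materials):
        # SizeDistribution enforces sorted diameters, so permutation
        # invariance is exercised through the input diameter list order
        d1 = pl.build_distribution([4.0, 18.0, 4.0, 18.0, 18.0], 1.0)
        d2 = pl.build_distribution([18.0, 4.0, 18.0, 4.0, 18.0], 1.0)
        np.testing.assert_allclose(d1.volume_fraction, d2.volume_fraction)

    def test_interpolation_step(self):
        dist = small_dist()
        fine = interpolate_distribution(dist, 0.1)
        assert np.allclose(np.diff(fine.diameters_um), 0.1)
        assert fine.number_fraction.sum() == pytest.approx(1.0)
        assert fine.volume_fraction.sum() == pytest.approx(1.0)


class TestReducedScattering:
    def test_isotropic_identity(self):
        assert pl.reduced_scattering(12.0, 0.0) == 12.0

    def test_a_series_worked_example(self):
        # mu_s(600 nm) at 1.5% volume fraction from the per-1% value of 31
        assert round(pl.reduced_scattering(31.0 * 1.5, 0.824), 1) == 8.2

    def test_d_series_worked_example(self):
        assert round(pl.reduced_scattering(31.0 * 7.3, 0.824), 1) == 39.8

    def test_invalid_g_rejected(self):
        with pytest.raises(ParameterError):
            pl.reduced_scattering(10.0, 1.5)


class TestFractionConversions:
    def test_equal_densities_identity(self):
        assert pl.mass_to_volume_fraction(0.3, 1.0) == pytest.approx(0.3)

    def test_a_series_mass_fraction(self):
        assert pl.mass_to_volume_fraction(0.017, 1.196) == pytest.approx(
            0.01426, abs=5e-5
        )

    def test_d_series_mass_fraction(self):
        assert pl.mass_to_volume_fraction(0.075, 1.196) == pytest.approx(
            0.0635, abs=5e-5
        )

    def test_volume_to_mass_worked_example(self):
        assert pl.volume_to_mass_fraction(0.0635, 1.196) == pytest.approx(
            0.075, abs=5e-5
        )

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, w):
        v = pl.mass_to_volume_fraction(w, 1.196)
        assert pl.volume_to_mass_fraction(v, 1.196) == pytest.approx(w, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            pl.mass_to_volume_fraction(1.2, 1.196)


class TestWallModel:
    def test_default_is_box_07_to_11(self, wall_model):
        np.testing.assert_allclose(
            wall_model.thicknesses_um, [0.7, 0.8, 0.9, 1.0, 1.1]
        )
        np.testing.assert_allclose(wall_model.weights, 0.2)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ParameterError):
            pl.WallThicknessModel(np.array([0.7, 0.9]), np.array([0.7, 0.7]))
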