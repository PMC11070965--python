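"""Photon Monte Carlo: sampling, conservation, benchmarks, determinism."""

import numpy as np
import pytest

import phantomlab as pl
from phantomlab.errors import ConfigurationError, ParameterError
from phantomlab.transport import (
    Layer,
    trace_semi_infinite_paths,
    spectral_path_sets,
)

from oracles import ISOTROPIC_A09_REFLECTANCE, semi_infinite_mc_oracle


class TestHGSampling:
    def test_isotropic_limit(self):
        rng = np.random.default_rng(1)
        s = np.array([pl.hg_sample(0.0, u) for u in rng.random(100_000)])
        assert abs(s.mean()) < 3 / np.sqrt(100_000)

    def test_mean_cosine_equals_g(self):
        g = 0.824
        rng = np.random.default_rng(2)
        s = np.array([pl.hg_sample(g, u) for u in rng.random(200_000)])
        se = s.std() / np.sqrt(s.size)
        assert abs(s.mean() - g) < 3 * se

    @pytest.mark.parametrize("g", [-0.9, 0.0, 0.9])
    def test_range(self, g):
        rng = np.random.default_rng(3)
        s = np.array([pl.hg_sample(g, u) for u in rng.random(50_000)])
        assert s.min() >= -1.0 and s.max() <= 1.0

    def test_invalid_g_rejected(self):
        with pytest.raises(ParameterError):
            pl.hg_sample(1.0, 0.5)


class TestSimulate:
    def test_pure_absorber_has_no_diffuse_reflectance(self):
        r = pl.simulate_reflectance(
            [Layer.semi_infinite(10.0, 0.0, 0.0, 1.0)], 1.0, 20_000, seed=1
        )
        assert r.diffuse_reflectance == 0.0
        assert r.specular_reflectance == 0.0
        assert r.absorbed_fraction == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_energy_conservation_random_configs(self, seed):
        rng = np.random.default_rng(100 + seed)
        layers = [
            Layer(
                thickness_cm=float(rng.uniform(0.02, 0.5)),
                mu_a=float(rng.uniform(0.1, 20.0)),
                mu_s=float(rng.uniform(1.0, 200.0)),
                g=float(rng.uniform(-0.5, 0.95)),
                n=float(rng.uniform(1.0, 1.6)),
            )
            for _ in range(rng.integers(1, 4))
        ]
        r = pl.simulate_reflectance(layers, 1.0, 20_000, seed=seed)
        se = max(r.std_error(r.diffuse_reflectance), r.std_error(r.absorbed_fraction))
        assert abs(r.total - 1.0) <= 3 * se + 1e-9

    def test_bit_identical_reproducibility(self):
        layer = [Layer.semi_infinite(1.0, 50.0, 0.8, 1.4)]
        a = pl.simulate_reflectance(layer, 1.0, 5_000, seed=42)
        b = pl.simulate_reflectance(layer, 1.0, 5_000, seed=42)
        assert a.diffuse_reflectance == b.diffuse_reflectance
        assert a.absorbed_fraction == b.absorbed_fraction

    def test_van_de_hulst_slab(self):
        """Optical depth 2 slab, albedo 0.9, g=0.75, matched: R=0.09739, T=0.66096."""
        r = pl.simulate_reflectance(
            [Layer(0.02, 10.0, 90.0, 0.75, 1.0)], 1.0, 200_000, seed=11
        )
        assert r.diffuse_reflectance == pytest.approx(
            0.09739, abs=3 * r.std_error(0.09739)
        )
        assert r.transmitted_fraction == pytest.approx(
            0.66096, abs=3 * r.std_error(0.66096)
        )

    def test_semi_infinite_isotropic_exact(self):
        """Matched semi-infinite, albedo 0.9, isotropic: plane albedo 0.41495
        (Chandrasekhar H-function)."""
        r = pl.simulate_reflectance(
            [Layer.semi_infinite(10.0, 90.0, 0.0, 1.0)], 1.0, 100_000, seed=5
        )
        assert r.diffuse_reflectance == pytest.approx(
            ISOTROPIC_A09_REFLECTANCE, abs=3 * r.std_error(0.415)
        )

    def test_matches_independent_mc_oracle(self):
        rd_o = semi_infinite_mc_oracle(10.0, 90.0, 0.75, 150_000, seed=21)
        r = pl.simulate_reflectance(
            [Layer.semi_infinite(10.0, 90.0, 0.75, 1.0)], 1.0, 150_000, seed=22
        )
        se = r.std_error(r.diffuse_reflectance)
        assert r.diffuse_reflectance == pytest.approx(rd_o, abs=4.5 * se)

    def test_monotone_in_mu_a(self):
        rds = []
        for mu_a in (0.2, 1.0, 3.0, 8.0, 20.0):
            r = pl.simulate_reflectance(
                [Layer.semi_infinite(mu_a, 90.0, 0.8, 1.4)], 1.0, 30_000, seed=9
            )
            rds.append(r.diffuse_reflectance)
        assert all(a > b for a, b in zip(rds, rds[1:]))

    def test_low_photon_warning_flag(self):
        r = pl.simulate_reflectance(
            [Layer.semi_infinite(1.0, 10.0, 0.5, 1.4)], 1.0, 999, seed=0
        )
        assert r.low_photon_warning

    def test_empty_stack_rejected(self):
        with pytest.raises(ConfigurationError):
            pl.simulate_reflectance([], 1.0, 1000, 0)


class TestScaledPathEngine:
    def test_matches_layered_kernel(self):
        """Dual route: scaled path estimator vs weighted multi-layer kernel."""
        ps = trace_semi_infinite_paths(0.824, 1.41, 1.0, 150_000, seed=3)
        for mu_a, mu_s in [(1.0, 226.3), (0.11, 46.5), (3.0, 100.0)]:
            rd = ps.reflectance(mu_a, mu_s)
            se = ps.reflectance_se(mu_a, mu_s)
            ref = pl.simulate_reflectance(
                [Layer.semi_infinite(mu_a, mu_s, 0.824, 1.41)], 1.0, 60_000, seed=8
            )
            tot_se = np.hypot(se, ref.std_error(ref.diffuse_reflectance))
            assert rd == pytest.approx(ref.diffuse_reflectance, abs=3.5 * tot_se)

    def test_zero_scattering_returns_zero(self):
        ps = trace_semi_infinite_paths(0.8, 1.4, 1.0, 10_000, seed=1)
        assert ps.reflectance(1.0, 0.0) == 0.0

    def test_black_medium(self):
        ps = trace_semi_infinite_paths(0.8, 1.4, 1.0, 20_000, seed=2)
        assert ps.reflectance(1.0e4, 50.0) <= 0.01

    def test_lossless_matched_conservation(self):
        """mu_a = 0, matched boundaries: every packet escapes one face of a
        lossless slab, so reflectance and transmittance sum to one exactly."""
        r = pl.simulate_reflectance(
            [Layer(0.5, 0.0, 80.0, 0.5, 1.0)], 1.0, 20_000, seed=4
        )
        total = (
            r.diffuse_reflectance + r.specular_reflectance + r.transmitted_fraction
        )
        assert total == pytest.approx(1.0)
        assert r.absorbed_fraction == 0.0

    def test_estimator_at_design_floor(self):
        """At mu_a/mu_s equal to the kill rate the path weights are all unity;
        the estimate must agree with the weighted kernel."""
        ps = trace_semi_infinite_paths(0.5, 1.0, 1.0, 60_000, seed=4)
        mu_s = 80.0
        mu_a = ps.kill_rate * mu_s
        rd = ps.reflectance(mu_a, mu_s)
        se = ps.reflectance_se(mu_a, mu_s)
        ref = pl.simulate_reflectance(
            [Layer.semi_infinite(mu_a, mu_s, 0.5, 1.0)], 1.0, 60_000, seed=5
        )
        tot = np.hypot(se, ref.std_error(ref.diffuse_reflectance))
        assert rd == pytest.approx(ref.diffuse_reflectance, abs=3.5 * tot)

    def test_clt_consistency_on_doubling(self):
        a = trace_semi_infinite_paths(0.8, 1.4, 1.0, 20_000, seed=6)
        b = trace_semi_infinite_paths(0.8, 1.4, 1.0, 40_000, seed=7)
        rd_a, rd_b = a.reflectance(1.0, 100.0), b.reflectance(1.0, 100.0)
        se = np.hypot(a.reflectance_se(1.0, 100.0), b.reflectance_se(1.0, 100.0))
        assert abs(rd_a - rd_b) < 3 * se

    def test_similarity_relation(self):
        """(mu_s, g) vs (mu_s(1-g)/(1-g'), g') within ~2% in the diffusive regime."""
        mu_a, mu_s, g, g2 = 0.3, 300.0, 0.824, 0.5
        ps1 = trace_semi_infinite_paths(g, 1.41, 1.0, 120_000, seed=10)
        ps2 = trace_semi_infinite_paths(g2, 1.41, 1.0, 120_000, seed=11)
        r1 = ps1.reflectance(mu_a, mu_s)
        r2 = ps2.reflectance(mu_a, mu_s * (1 - g) / (1 - g2))
        assert r2 == pytest.approx(r1, rel=0.02)


class TestSpectral:
    def test_spectrum_deterministic_and_smooth_interface(self, fit_grid_20):
        m = len(fit_grid_20)
        props = pl.OpticalProperties(
            fit_grid_20,
            mu_a=np.full(m, 1.0),
            mu_s=np.full(m, 150.0),
            g=np.full(m, 0.8),
            n=np.full(m, 1.41),
        )
        a = pl.spectral_reflectance(props, 1.0, 20_000, seed=3)
        b = pl.spectral_reflectance(props, 1.0, 20_000, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.kind == "reflectance"

    def test_substream_seeds_distinct(self):
        seeds = {pl.substream_seed(5, i) for i in range(100)}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)

    def test_path_sets_reused_bit_identical(self, fit_grid_20):
        m = len(fit_grid_20)
        g = np.full(m, 0.8)
        n = np.full(m, 1.41)
        sets = spectral_path_sets(g, n, 1.0, 10_000, seed=9)
        props = pl.OpticalProperties(
            fit_grid_20, np.full(m, 0.5), np.full(m, 120.0), g, n
        )
        a = pl.spectral_reflectance(props, 1.0, 10_000, 9, path_sets=sets)
        b = pl.spectral_reflectance(props, 1.0, 10_000, 9)
        np.testing.assert_array_equal(a.values, b.values)
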