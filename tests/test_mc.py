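"""Monte Carlo slab transport: samplers, boundaries, scoring, physics checks."""

import math

import numpy as np
import pytest
from scipy import stats

from slablight import (
    MCConfig,
    OpticalProperties,
    SlabGeometry,
    absorption_map,
    fresnel_reflectance,
    iso_level_depth,
    km_forward,
    mc_run,
    sample_hg,
    sample_step,
    validate_against_twoflux,
)
from slablight.errors import ConfigError

from conftest import G, ROWS_800, THICKNESS, standard_error

MATCHED = SlabGeometry(THICKNESS, 1.0, 1.0, 1.0)


class TestSamplers:
    def test_step_examples(self):
        assert sample_step(1.0, 134.11) == 0.0
        assert sample_step(math.exp(-1), 134.11) == pytest.approx(1 / 134.11)

    def test_step_rejects_zero(self):
        with pytest.raises(ValueError):
            sample_step(0.0, 10.0)

    def test_step_mean_is_mean_free_path(self):
        rng = np.random.default_rng(11)
        mu_t = 134.11
        s = sample_step(1 - rng.random(200_000), mu_t)
        se = s.std() / math.sqrt(s.size)
        assert abs(s.mean() - 1 / mu_t) < 3 * se

    def test_hg_isotropic_inverse_cdf(self):
        assert sample_hg(0.75, 0.0) == pytest.approx(0.5)

    def test_hg_mean_equals_g(self):
        rng = np.random.default_rng(12)
        ct = sample_hg(rng.random(1_000_000), G)
        se = ct.std() / 1000.0
        assert abs(ct.mean() - G) < 3 * se

    def test_hg_isotropic_is_uniform(self):
        rng = np.random.default_rng(13)
        ct = sample_hg(rng.random(100_000), 0.0)
        stat = stats.kstest(ct, stats.uniform(loc=-1, scale=2).cdf)
        assert stat.pvalue > 0.01


class TestFresnel:
    def test_matched_boundary(self):
        assert fresnel_reflectance(1.33, 1.33, 0.7) == 0.0

    def test_normal_incidence(self):
        expected = ((1 - 1.54) / (1 + 1.54)) ** 2
        assert fresnel_reflectance(1.0, 1.54, 1.0) == pytest.approx(expected)

    def test_total_internal_reflection(self):
        cos_crit = math.sqrt(1 - (1 / 1.54) ** 2)
        assert fresnel_reflectance(1.54, 1.0, 0.5 * cos_crit) == 1.0


class TestTransport:
    def test_beer_lambert_without_scattering(self):
        # pure absorber, matched boundaries: T = exp(-mu_a t)
        mu_a = 20.0
        config = MCConfig(n_photons=100_000, seed=5, nz=50)
        res = mc_run(OpticalProperties(mu_a, 0.0, g=G, n=1.0), MATCHED, config)
        expected = math.exp(-mu_a * THICKNESS)
        se = standard_error(expected, config.n_photons)
        assert abs(res.t_diffuse_total - expected) < 3 * se
        assert res.r_diffuse_total == 0.0

    def test_no_absorption_all_weight_escapes(self, small_mc_config):
        res = mc_run(
            OpticalProperties(0.0, 120.0, g=G, n=1.0), MATCHED, small_mc_config
        )
        assert res.a_total == pytest.approx(0.0, abs=1e-12)
        assert res.r_diffuse_total + res.t_diffuse_total == pytest.approx(
            1.0, abs=1e-9
        )

    def test_weight_conservation_exact(self, props_800_p0, small_mc_config):
        geometry = SlabGeometry(THICKNESS, 1.54, 1.0, 1.0)
        res = mc_run(props_800_p0, geometry, small_mc_config)
        assert abs(res.total_accounted - 1.0) < 1e-9

    def test_bit_reproducible(self, props_800_p0, small_mc_config):
        a = mc_run(props_800_p0, MATCHED, small_mc_config)
        b = mc_run(props_800_p0, MATCHED, small_mc_config)
        assert a.r_diffuse_total == b.r_diffuse_total
        assert a.t_diffuse_total == b.t_diffuse_total
        np.testing.assert_array_equal(a.a_rz, b.a_rz)
        np.testing.assert_array_equal(a.r_angular, b.r_angular)

    def test_convergence_scales_inverse_sqrt_n(self, props_800_p0):
        # sd of scored reflectance across replicates should shrink ~ 1/sqrt(n)
        def spread(n_photons, base_seed):
            vals = [
                mc_run(
                    props_800_p0,
                    MATCHED,
                    MCConfig(n_photons=n_photons, seed=base_seed + i, nz=20, nr=20),
                ).r_diffuse_total
                for i in range(12)
            ]
            return np.std(vals)

        s_small = spread(1_000, 100)
        s_big = spread(16_000, 200)
        ratio = s_small / s_big  # expect ~ sqrt(16) = 4
        assert 2.0 < ratio < 8.0

    def test_isotropic_azimuthal_symmetry(self):
        # with g = 0 the reflected weight is uniform over the 48 phi bins;
        # a non-absorbing medium makes every escape a unit-weight count, so
        # the chi-square multinomial test applies exactly
        config = MCConfig(n_photons=60_000, seed=21, nz=50)
        res = mc_run(
            OpticalProperties(0.0, 50.0, g=0.0, n=1.0), MATCHED, config
        )
        counts = res.r_angular.sum(axis=0) * config.n_photons
        stat = stats.chisquare(counts)
        assert stat.pvalue > 0.01

    def test_published_slab_benchmark(self):
        # mu_a=10, mu_s=90, g=0.75, t=0.02 cm, matched boundaries:
        # R_d = 0.09739, T_d = 0.66096 (published MCML validation values)
        config = MCConfig(n_photons=150_000, seed=3, nz=50)
        res = mc_run(
            OpticalProperties(10.0, 90.0, g=0.75, n=1.0),
            SlabGeometry(0.02, 1.0, 1.0, 1.0),
            config,
        )
        assert res.r_diffuse_total == pytest.approx(0.09739, abs=0.003)
        assert res.t_diffuse_total == pytest.approx(0.66096, abs=0.005)

    def test_semi_infinite_mismatched_benchmark(self):
        # albedo 0.9, g=0, relative index 1.5: total R = 0.26139 (Giovanelli)
        config = MCConfig(n_photons=100_000, seed=3, nz=100, dz=0.1)
        res = mc_run(
            OpticalProperties(10.0, 90.0, g=0.0, n=1.5),
            SlabGeometry(10.0, 1.5, 1.0, 1.0),
            config,
        )
        assert res.r_total == pytest.approx(0.26139, abs=0.006)

    def test_rejects_non_interacting_medium(self, small_mc_config):
        with pytest.raises(ValueError):
            mc_run(OpticalProperties(0.0, 0.0, g=G), MATCHED, small_mc_config)

    def test_rejects_grid_not_covering_slab(self, props_800_p0):
        config = MCConfig(n_photons=10, nz=10, dz=0.001)
        with pytest.raises(ConfigError):
            mc_run(props_800_p0, MATCHED, config)


class TestAbsorptionMap:
    def test_fraction_grid_accounts_for_absorbed_weight(
        self, props_800_p0, small_mc_config
    ):
        res = mc_run(props_800_p0, MATCHED, small_mc_config)
        grid = absorption_map(res, "fraction")
        # grid holds deposits incl. roulette kills; a_total subtracts the boost
        assert grid.sum() == pytest.approx(res.a_total + res.roulette_boost, abs=1e-12)
        assert grid.min() >= 0

    def test_per_area_normalization(self, props_800_p0, small_mc_config):
        res = mc_run(props_800_p0, MATCHED, small_mc_config)
        frac = absorption_map(res, "fraction")
        per_area = absorption_map(res, "per_area")
        edges = res.dr * np.arange(frac.shape[0] + 1)
        area = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        np.testing.assert_allclose(
            per_area * area[:, None] / res.n_photons_run, frac, rtol=1e-12
        )
        per_vol = absorption_map(res, "per_volume")
        np.testing.assert_allclose(per_vol * res.dz, per_area, rtol=1e-12)

    def test_unknown_normalization(self, props_800_p0, small_mc_config):
        res = mc_run(props_800_p0, MATCHED, small_mc_config)
        with pytest.raises(ConfigError):
            absorption_map(res, "per_steradian")

    def test_irradiated_sample_absorbs_deeper(self, small_mc_config):
        # the 30 kGy sample has the lower mu_eff, hence the deeper iso level
        geometry = SlabGeometry(THICKNESS, 1.54, 1.0, 1.0)
        depths = {}
        for dose in ("P-0", "P-30"):
            res = mc_run(
                OpticalProperties(*ROWS_800[dose], g=G), geometry, small_mc_config
            )
            depths[dose] = iso_level_depth(res)
        assert depths["P-30"] >= depths["P-0"]


class TestValidation:
    def test_report_structure(self, props_800_p0, small_mc_config):
        rep = validate_against_twoflux(props_800_p0, MATCHED, small_mc_config)
        assert set(rep["relative_difference"]) == {"R", "T", "A"}
        assert rep["max_relative_difference"] == max(
            rep["relative_difference"].values()
        )
        assert rep["passed"] == (rep["max_relative_difference"] <= rep["threshold"])
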