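"""Synthetic-city generator: geometry, determinism, truth recoverability."""

import numpy as np
import pandas as pd
import pytest

from lurex.buffers import build_feature_table
from lurex.lur import stepwise_select
from lurex.raster import GridRaster, extract_at_points
from lurex.synthetic import (DEFAULT_DIURNAL_PROFILES, DEFAULT_PHONE_ON_PROB,
                             CityConfig, TrueModel, gen_agents,
                             gen_covariate_rasters, gen_rings,
                             gen_site_observations, gen_station_counts,
                             gen_truth_surface, generate_city, place_sites,
                             place_stations)

# a light config used throughout: 40x40 grid, small population
SMALL = dict(domain_size_m=(18000.0, 18000.0), cell_size_m=450.0,
             n_sites=12, n_stations=60, n_agents=2000,
             n_days_per_season=2, correlation_length_m=2250.0,
             ring_radii_m=(2000.0, 3000.0, 4000.0, 5000.0),
             core_sigma_m=2500.0)


@pytest.fixture()
def small_config():
    return CityConfig(**SMALL)


class TestConfigValidation:
    def test_domain_must_be_cell_multiple(self):
        with pytest.raises(ValueError, match="integer multiples"):
            CityConfig(domain_size_m=(1000.0, 900.0), cell_size_m=450.0)

    def test_phone_on_prob_range_checked(self):
        bad = np.full(24, 1.5)
        with pytest.raises(ValueError, match="phone_on_prob"):
            CityConfig(**{**SMALL, "phone_on_prob": bad})

    def test_diurnal_profile_must_be_positive(self):
        bad = {k: v.copy() for k, v in DEFAULT_DIURNAL_PROFILES.items()}
        bad["spring"] = np.zeros(24)
        with pytest.raises(ValueError, match="positive"):
            CityConfig(**{**SMALL, "diurnal_profiles": bad})

    def test_ring_radii_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            CityConfig(**{**SMALL, "ring_radii_m": (3000.0, 2000.0)})

    def test_default_profiles_have_unit_mean(self):
        for prof in DEFAULT_DIURNAL_PROFILES.values():
            assert prof.mean() == pytest.approx(1.0, abs=1e-12)
            assert (prof > 0).all()


class TestCovariateRasters:
    def test_dts_at_south_edge_is_half_cell_in_km(self, small_config):
        dts = gen_covariate_rasters(small_config)["DTS"]
        assert dts.values[-1, 0] == pytest.approx(
            small_config.cell_size_m / 2 / 1000.0)
        assert dts.units == "km"

    def test_dts_constant_along_rows_increasing_northward(self, small_config):
        dts = gen_covariate_rasters(small_config)["DTS"]
        assert np.all(np.ptp(dts.values, axis=1) == 0.0)
        col = dts.values[:, 0]
        assert np.all(np.diff(col) < 0)  # row 0 is the north edge

    def test_same_seed_bit_identical(self, small_config):
        a = gen_covariate_rasters(small_config)
        b = gen_covariate_rasters(small_config)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_shared_grid_geometry(self, small_config):
        rasters = gen_covariate_rasters(small_config)
        ref = rasters["DTS"]
        assert all(r.same_geometry(ref) for r in rasters.values())

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            CityConfig(**{**SMALL, "cell_size_m": -1.0})


class TestTruthSurface:
    def test_zero_coefficients_give_intercept(self, small_config):
        rasters = gen_covariate_rasters(small_config)
        truth = gen_truth_surface(rasters, TrueModel(50.0, ()))
        np.testing.assert_allclose(truth.values, 50.0)

    def test_printed_intercept_at_zero_covariates(self):
        zeros = GridRaster(np.zeros((8, 8)), cell_size_m=450.0)
        rasters = {"DTS": zeros, "Slope": zeros.with_values(np.zeros((8, 8)))}
        truth = gen_truth_surface(
            rasters, TrueModel(115.83, (("DTS", 2400.0, -0.48),
                                        ("Slope", 4620.0, -1.15))))
        np.testing.assert_allclose(truth.values, 115.83)

    def test_one_term_arithmetic(self):
        const3 = GridRaster(np.full((6, 6), 3.0), cell_size_m=450.0)
        truth = gen_truth_surface({"C": const3},
                                  TrueModel(1.0, (("C", 450.0, 2.0),)))
        np.testing.assert_allclose(truth.values, 7.0)

    def test_unknown_covariate_named(self, small_config):
        rasters = gen_covariate_rasters(small_config)
        with pytest.raises(KeyError, match="Bogus"):
            gen_truth_surface(rasters, TrueModel(1.0, (("Bogus", 450.0, 1.0),)))

    def test_floored_at_zero(self):
        big = GridRaster(np.full((6, 6), 100.0), cell_size_m=450.0)
        truth = gen_truth_surface({"C": big},
                                  TrueModel(10.0, (("C", 450.0, -5.0),)))
        np.testing.assert_allclose(truth.values, 0.0)


class TestSiteObservations:
    def test_noise_free_flat_profile_equals_truth(self, small_config, rng):
        from dataclasses import replace
        flat = {s: np.ones(24) for s in small_config.seasons}
        cfg = replace(small_config, noise_sd_ugm3=0.0, outlier_fraction=0.0,
                      missing_fraction=0.0, diurnal_profiles=flat)
        rasters = gen_covariate_rasters(cfg)
        truths = {s: gen_truth_surface(rasters, cfg.true_model_for(s))
                  for s in cfg.seasons}
        sites = place_sites(cfg, rasters["Road"], rng)
        obs = gen_site_observations(truths, sites, cfg)
        for season in cfg.seasons:
            at_site = dict(zip(sites["site_id"],
                               extract_at_points(truths[season],
                                                 sites["x"], sites["y"])))
            sub = obs[obs["season"] == season]
            expect = sub["site_id"].map(at_site)
            np.testing.assert_allclose(sub["pm25"], expect)

    def test_outlier_count_near_binomial_expectation(self, rng):
        cfg = CityConfig(**{**SMALL, "n_sites": 35, "n_days_per_season": 90,
                            "seasons": ("spring",),
                            "outlier_fraction": 0.01,
                            "missing_fraction": 0.0})
        rasters = gen_covariate_rasters(cfg)
        truths = {"spring": gen_truth_surface(rasters,
                                              cfg.true_model_for("spring"))}
        sites = place_sites(cfg, rasters["Road"], rng)
        obs = gen_site_observations(truths, sites, cfg)
        n_out = int((obs["pm25"] > 1000).sum())
        expect = 35 * 24 * 90 * 0.01  # = 756
        assert abs(n_out - expect) < 5 * np.sqrt(expect)
        assert (obs.loc[obs["pm25"] > 1000, "pm25"] > 1000).all()

    def test_missing_fraction_removes_about_ten_percent(self, small_config, rng):
        from dataclasses import replace
        cfg = replace(small_config, missing_fraction=0.1,
                      n_days_per_season=10)
        rasters = gen_covariate_rasters(cfg)
        truths = {s: gen_truth_surface(rasters, cfg.true_model_for(s))
                  for s in cfg.seasons}
        sites = place_sites(cfg, rasters["Road"], rng)
        obs = gen_site_observations(truths, sites, cfg)
        full = cfg.n_sites * 24 * 10 * len(cfg.seasons)
        assert 1 - len(obs) / full == pytest.approx(0.1, abs=0.02)

    def test_underdetermined_site_count_warns(self, small_config, rng):
        from dataclasses import replace
        cfg = replace(small_config, n_sites=4)
        rasters = gen_covariate_rasters(cfg)
        truths = {s: gen_truth_surface(rasters, cfg.true_model_for(s))
                  for s in cfg.seasons}
        sites = place_sites(cfg, rasters["Road"], rng)
        with pytest.warns(UserWarning, match="underdetermined"):
            gen_site_observations(truths, sites, cfg)


class TestStationCounts:
    def test_always_on_static_agents_constant_columns(self, small_config, rng):
        from dataclasses import replace
        cfg = replace(small_config, phone_on_prob=np.ones(24),
                      commuter_fraction=0.0)
        stations = place_stations(cfg, rng)
        agents = gen_agents(stations, cfg)
        counts = gen_station_counts(agents, stations, cfg)
        totals = counts.hourly_totals()
        assert np.all(totals == cfg.n_agents)
        assert np.all(counts.counts == counts.counts[:, [0]])

    def test_night_day_ratio_follows_phone_on_prob(self, small_config, rng):
        prob = np.where((np.arange(24) >= 8) & (np.arange(24) < 20), 0.9, 0.25)
        from dataclasses import replace
        cfg = replace(small_config, phone_on_prob=prob, n_agents=20000)
        stations = place_stations(cfg, rng)
        agents = gen_agents(stations, cfg)
        counts = gen_station_counts(agents, stations, cfg)
        totals = counts.hourly_totals()
        ratio = totals[2] / totals[12]
        assert ratio == pytest.approx(0.25 / 0.9, rel=0.06)

    def test_same_seed_identical_counts(self, small_config):
        a = generate_city(small_config, seed=5)
        b = generate_city(small_config, seed=5)
        np.testing.assert_array_equal(a.counts.counts, b.counts.counts)

    def test_schedule_has_24_entries_and_valid_indices(self, small_config, rng):
        stations = place_stations(small_config, rng)
        agents = gen_agents(stations, small_config)
        assert agents.schedule.shape == (small_config.n_agents, 24)
        for arr in (agents.home_station, agents.work_station,
                    agents.transit_station):
            assert arr.min() >= 0 and arr.max() < len(stations)


class TestRings:
    def test_four_radii_give_five_partitioning_zones(self, small_config):
        rings = gen_rings(small_config)
        assert len(rings.zone_labels) == 5
        zones = rings.zone_polygons()
        total = sum(z.area for z in zones.values())
        lx, ly = small_config.domain_size_m
        assert total == pytest.approx(lx * ly, rel=1e-9)

    def test_every_point_in_exactly_one_zone(self, small_config, rng):
        rings = gen_rings(small_config)
        zones = rings.zone_polygons()
        from shapely.geometry import Point
        lx, ly = small_config.domain_size_m
        for _ in range(50):
            p = Point(rng.uniform(0, lx), rng.uniform(0, ly))
            hits = [lab for lab, z in zones.items()
                    if z.contains(p) or z.touches(p)]
            assert len({*hits}) >= 1  # on shared edges touches can double
            assert rings.zone_of(p.x, p.y) in rings.zone_labels


class TestTruthRecoverability:
    def test_noise_free_refit_returns_true_coefficients(self, small_config, rng):
        """With zero noise and features built at the true buffer radii, the
        regression chain returns the generator's coefficients exactly."""
        from dataclasses import replace
        cfg = replace(small_config, noise_sd_ugm3=0.0, outlier_fraction=0.0,
                      missing_fraction=0.0, n_sites=20)
        rasters = gen_covariate_rasters(cfg)
        truth = gen_truth_surface(rasters, cfg.true_model)
        sites = place_sites(cfg, rasters["Road"], rng)
        response = extract_at_points(truth, sites["x"], sites["y"])
        radii = {cov: r for cov, r, _ in cfg.true_model.terms}
        feats = build_feature_table(
            {c: rasters[c] for c in radii}, radii, sites, response)
        model = stepwise_select(feats)
        got = {t.covariate: t.coefficient for t in model.terms}
        for cov, _, coef in cfg.true_model.terms:
            assert got[cov] == pytest.approx(coef, rel=1e-6)
        assert model.intercept == pytest.approx(cfg.true_model.intercept,
                                                rel=1e-6)


def test_full_city_generation_is_deterministic(small_config):
    a = generate_city(small_config, seed=3)
    b = generate_city(small_config, seed=3)
    pd.testing.assert_frame_equal(a.observations, b.observations)
    pd.testing.assert_frame_equal(a.stations, b.stations)
    np.testing.assert_array_equal(a.truths["yearly"].values,
                                  b.truths["yearly"].values)


def test_phone_on_default_swings_severalfold():
    ratio = DEFAULT_PHONE_ON_PROB.min() / DEFAULT_PHONE_ON_PROB.max()
    assert ratio < 0.4  # night totals well under half the day peak
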