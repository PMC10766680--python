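"""Tree demography, seed dispersal, establishment, litter, and active layer."""

import numpy as np
import pandas as pd
import pytest

import firelarch as fl
from firelarch.forest import (ForestParams, LitterParams, Tree,
                              active_layer_equilibrium, germination_probability,
                              height_increment)
from firelarch.climate import thaw_index


def stationary_thaw_index():
    """Degree-day index of the default (noise-free) synthetic climate."""
    clim = fl.generate_synthetic_climate(
        1, fl.SyntheticClimateParams(t_noise_sd=0.0), seed=0)
    return thaw_index(clim["t_mon"].to_numpy())


def one_year_climate(t_const=11.5):
    return pd.DataFrame({"year": 0, "month": np.arange(1, 13), "t_mon": t_const,
                         "p_mon": 20.0})


class TestGrowth:
    def test_infinite_competition_stops_growth(self, species):
        tr = species["Dahurian larch"]
        dh = height_increment(100.0, tr, tr.temp_optimum_c, 1e12)
        assert dh == pytest.approx(0.0, abs=1e-6)

    def test_optimal_conditions_give_full_rate(self, species):
        tr = species["Dahurian larch"]
        tree = Tree("Dahurian larch", 1.0, 1.0, height=100.0)
        h = fl.annual_growth(tree, one_year_climate(tr.temp_optimum_c), 0.0, tr)
        assert h - 100.0 == pytest.approx(tr.growth_rate_cm_per_yr)

    def test_cold_growth_slower_than_optimal(self, species):
        tr = species["Dahurian larch"]
        dh_cold = height_increment(100.0, tr, tr.temp_optimum_c - 5.0, 0.0)
        dh_opt = height_increment(100.0, tr, tr.temp_optimum_c, 0.0)
        assert dh_cold < dh_opt

    def test_height_asymptote_bounds_growth(self, species):
        tr = species["Dahurian larch"]
        h = 100.0
        for _ in range(3000):
            h += height_increment(h, tr, tr.temp_optimum_c, 0.0)
        assert h <= tr.max_height_cm + 1e-6

    def test_crown_base_stays_below_height(self, species):
        tr = species["Dahurian larch"]
        tree = Tree("Dahurian larch", 0.0, 0.0, height=50.0, crown_base=10.0)
        for _ in range(200):
            fl.annual_growth(tree, one_year_climate(tr.temp_optimum_c), 0.5, tr)
            assert 0.0 <= tree.crown_base < tree.height


class TestCompetition:
    def test_isolated_tree_scores_zero(self):
        assert fl.competition_index(100.0, [], []) == 0.0

    def test_adding_neighbor_never_decreases_index(self, rng):
        heights = rng.uniform(50, 1200, 30)
        dists = rng.uniform(0.5, 9.5, 30)
        base = 0.0
        for k in range(1, 31):
            ci = fl.competition_index(100.0, heights[:k], dists[:k])
            assert ci >= base - 1e-12
            base = ci

    def test_thinning_releases_crowded_tree(self, rng):
        heights = np.full(20, 800.0)
        dists = rng.uniform(1.0, 9.0, 20)
        full = fl.competition_index(300.0, heights, dists)
        half = fl.competition_index(300.0, heights[:10], dists[:10])
        assert half < full

    def test_shorter_neighbors_do_not_shade(self):
        assert fl.competition_index(500.0, [100.0, 499.0], [2.0, 3.0]) == 0.0

    def test_vectorized_matches_scalar(self, rng):
        n = 40
        x = rng.uniform(0, 30, n)
        y = rng.uniform(0, 30, n)
        h = rng.uniform(10, 1200, n)
        ci_vec = fl.competition_indices(x, y, h)
        params = ForestParams()
        for i in range(n):
            d = np.hypot(x - x[i], y - y[i])
            others = (np.arange(n) != i) & (d < params.competition_radius_m)
            ci_scalar = fl.competition_index(h[i], h[others], d[others], params)
            assert ci_vec[i] == pytest.approx(ci_scalar, rel=1e-9, abs=1e-12)


class TestSeeds:
    def _pop_with_tree(self, species, height, landscape, sp="Dahurian larch"):
        pop = fl.TreePopulation(list(species))
        # parent at a fine-cell center (not on a cell boundary)
        x = landscape.width_m / 2 + landscape.fine_res_m / 2
        pop.add(pop.species_index(sp), x, x, height=height, crown_base=0.0, age=50)
        return pop

    def test_immature_tree_produces_nothing(self, species, small_landscape, rng):
        pop = self._pop_with_tree(species, 100.0, small_landscape)
        small_landscape.ground_seeds.clear()
        n = fl.produce_and_disperse(pop, small_landscape, species, rng)
        assert n == 0 and pop.cone_seeds[0] == 0

    def test_zero_sd_lands_in_parent_cell(self, species, small_landscape, rng):
        traits = dict(species)
        traits["Dahurian larch"] = fl.SpeciesTraits(
            **{**traits["Dahurian larch"].__dict__, "dispersal_sd_m": 1e-9})
        pop = self._pop_with_tree(traits, 800.0, small_landscape)
        small_landscape.ground_seeds.clear()
        n = fl.produce_and_disperse(pop, small_landscape, traits, rng)
        grid = small_landscape.seed_grid("Dahurian larch")
        r, c = small_landscape.fine_index(pop.x[0], pop.y[0])
        assert n > 0 and grid[r, c] == n

    def test_mean_dispersal_distance_is_rayleigh(self, species, rng):
        # isotropic Gaussian kernel => distance ~ Rayleigh(sd),
        # E[d] = sd * sqrt(pi/2)
        scape = fl.generate_synthetic_landscape(6, coarse_res_m=9.0, seed=3)
        sd = 2.0
        traits = dict(species)
        traits["Dahurian larch"] = fl.SpeciesTraits(
            **{**traits["Dahurian larch"].__dict__, "dispersal_sd_m": sd,
               "seeds_per_year": 20_000})
        pop = self._pop_with_tree(traits, 800.0, scape)
        scape.ground_seeds.clear()
        n = fl.produce_and_disperse(pop, scape, traits, rng)
        grid = scape.seed_grid("Dahurian larch")
        rr, cc = np.nonzero(grid)
        res = scape.fine_res_m
        d = np.hypot((cc + 0.5) * res - pop.x[0], (rr + 0.5) * res - pop.y[0])
        mean_d = float(np.average(d, weights=grid[rr, cc]))
        expected = sd * np.sqrt(np.pi / 2)
        se = sd * np.sqrt(2 - np.pi / 2) / np.sqrt(n)
        assert abs(mean_d - expected) < 3 * se + 0.2  # 0.2 m cell-rounding slack

    def test_seeds_never_land_on_water(self, species, wet_landscape, rng):
        pop = fl.TreePopulation(list(species))
        land_r, land_c = np.nonzero(wet_landscape.land_fine)
        res = wet_landscape.fine_res_m
        for k in range(0, land_r.size, max(1, land_r.size // 30)):
            pop.add(0, (land_c[k] + 0.5) * res, (land_r[k] + 0.5) * res,
                    height=900.0, crown_base=100.0, age=60)
        fl.produce_and_disperse(pop, wet_landscape, species, rng)
        for grid in wet_landscape.ground_seeds.values():
            assert grid[wet_landscape.water_fine].sum() == 0


class TestEstablish:
    def _prepared(self, scape, species, name, active_layer_cm, litter_cm=0.0,
                  seeds=2000):
        scape.active_layer_depth[:] = np.where(
            scape.land_fine, active_layer_cm, 0.0).astype(np.float32)
        scape.litter_height[:] = np.where(
            scape.land_fine, litter_cm, 0.0).astype(np.float32)
        scape.ground_seeds.clear()
        grid = scape.seed_grid(name)
        land_r, land_c = np.nonzero(scape.land_fine)
        grid[land_r[:seeds], land_c[:seeds]] = 1
        return scape

    def test_spruce_blocked_by_shallow_thaw(self, species, rng):
        scape = fl.generate_synthetic_landscape(4, coarse_res_m=9.0, seed=4)
        self._prepared(scape, species, "Siberian spruce", active_layer_cm=150.0)
        recruits = fl.establish(scape, species, rng)
        assert "Siberian spruce" not in recruits

    def test_larch_establishes_at_25cm_thaw(self, species, rng):
        scape = fl.generate_synthetic_landscape(4, coarse_res_m=9.0, seed=4)
        self._prepared(scape, species, "Dahurian larch", active_layer_cm=25.0)
        recruits = fl.establish(scape, species, rng)
        assert len(recruits.get("Dahurian larch", [])) > 0

    def test_germination_declines_with_litter(self):
        assert germination_probability(0.0) > germination_probability(13.0)

    def test_germinated_seeds_consumed(self, species, rng):
        scape = fl.generate_synthetic_landscape(4, coarse_res_m=9.0, seed=4)
        self._prepared(scape, species, "Dahurian larch", active_layer_cm=60.0)
        before = int(scape.seed_grid("Dahurian larch").sum())
        recruits = fl.establish(scape, species, rng)
        after = int(scape.seed_grid("Dahurian larch").sum())
        assert after < before  # germination + bank decay both consume


class TestMortality:
    def test_beyond_max_age_is_certain_death(self, species):
        tr = species["Dahurian larch"]
        assert fl.natural_mortality_prob(tr.max_age_yr, tr, 0.0) == 1.0
        assert fl.natural_mortality_prob(tr.max_age_yr + 10, tr, 0.0) == 1.0

    def test_young_uncrowded_tree_dies_at_background_rate(self, species):
        tr = species["Dahurian larch"]
        assert fl.natural_mortality_prob(20, tr, 0.0) \
            == pytest.approx(tr.background_mortality)

    def test_cohort_survival_geometric(self, species):
        # 10,000 uncrowded young trees: survival to age a ~ (1 - bg)^a
        tr = species["Dahurian larch"]
        rng = np.random.default_rng(404)
        n, a = 10_000, 20
        alive = np.ones(n, dtype=bool)
        p = fl.natural_mortality_prob(10, tr, 0.0)
        for _ in range(a):
            alive &= rng.random(n) >= p
        expected = (1 - tr.background_mortality) ** a
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(alive.mean() - expected) < 3 * se

    def test_dead_trees_stay_dead(self, species):
        pop = fl.TreePopulation(list(species))
        pop.add(0, [1.0, 2.0], [1.0, 2.0], height=100.0)
        pop.kill(np.array([True, False]))
        pop.kill(np.array([False, False]))  # no resurrection
        assert list(pop.alive) == [False, True]


class TestLitter:
    def test_deterministic_regrowth_half_cm_per_year(self):
        land = np.ones((5, 5), dtype=bool)
        litter = np.zeros((5, 5), dtype=np.float32)
        for _ in range(10):
            litter = fl.update_litter(litter, land, rng=None)
        np.testing.assert_allclose(litter, 5.0)

    def test_cap_and_nonnegativity(self, rng):
        land = np.ones((50, 50), dtype=bool)
        params = LitterParams(cap_cm=20.0)
        litter = np.full((50, 50), 19.9, dtype=np.float32)
        for _ in range(50):
            litter = fl.update_litter(litter, land, rng, params)
            assert litter.min() >= 0.0 and litter.max() <= 20.0

    def test_water_cells_hold_no_litter(self, rng):
        land = np.zeros((4, 4), dtype=bool)
        litter = fl.update_litter(np.zeros((4, 4), np.float32), land, rng)
        assert litter.max() == 0.0

    def test_calibration_formula(self):
        p = fl.calibrate_litter_disturbance(13.0, 0.5)
        assert p == pytest.approx(2.0 / 27.0)
        assert LitterParams().stationary_mean_cm() == pytest.approx(13.0)

    def test_foliage_supply_limits_growth(self):
        land = np.ones((3, 3), dtype=bool)
        litter = fl.update_litter(np.zeros((3, 3), np.float32), land, rng=None,
                                  foliage_supply=0.5)
        np.testing.assert_allclose(litter, 0.25)


class TestActiveLayer:
    def test_bare_ground_thaws_deeper_than_littered(self):
        ti = stationary_thaw_index()
        assert active_layer_equilibrium(ti, 0.0) > active_layer_equilibrium(ti, 13.0)

    def test_calibrated_equilibria(self):
        # c. 60 cm under 13 cm litter; c. 100 cm on near-bare ground,
        # both under the stationary synthetic climate
        ti = stationary_thaw_index()
        assert active_layer_equilibrium(ti, 13.0) == pytest.approx(60.0, abs=3.0)
        assert active_layer_equilibrium(ti, 1.0) == pytest.approx(100.0, abs=5.0)

    def test_monotone_convergence_to_fixed_point(self):
        ti = stationary_thaw_index()
        land = np.ones((3, 3), dtype=bool)
        litter = np.full((3, 3), 13.0, dtype=np.float32)
        depth = np.full((3, 3), 30.0, dtype=np.float32)
        eq = active_layer_equilibrium(ti, 13.0)
        prev_gap = np.inf
        for _ in range(100):
            depth = fl.update_active_layer(depth, ti, litter, land)
            gap = abs(float(depth[0, 0]) - eq)
            assert gap <= prev_gap + 1e-6  # contraction, no oscillation
            prev_gap = gap
        assert gap < 0.5
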