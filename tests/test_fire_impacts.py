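"""Fire impacts: tree mortality, seed destruction, litter consumption,
and whole-event bookkeeping."""

import dataclasses

import numpy as np
import pytest

import firelarch as fl
from firelarch.fire_impacts import (ImpactParams, bark_thickness_cm,
                                    crown_kill_prob, stem_kill_prob)
from firelarch.forest import Tree


class TestKillProbability:
    def test_no_fire_no_death(self, species, rng):
        tree = Tree("Dahurian larch", 1.0, 1.0, height=500.0, crown_base=150.0)
        alive, resprouted = fl.tree_fire_mortality(
            tree, 0.0, species["Dahurian larch"], rng)
        assert alive and not resprouted and tree.alive

    def test_full_intensity_kills_every_species_and_height(self, species):
        # stand-replacing anchor: p_kill >= 0.999 at FI = 1 everywhere
        heights = np.array([10.0, 50.0, 130.0, 500.0, 1000.0, 1440.0])
        for tr in species.values():
            h = np.minimum(heights, tr.max_height_cm - 1.0)
            p = fl.kill_probability(1.0, h, 0.35 * h, tr)
            assert np.all(p >= 0.999), tr.name

    def test_low_intensity_spares_tall_larch(self, species):
        tr = species["Dahurian larch"]
        p_tall = fl.kill_probability(0.1, 1000.0, 350.0, tr)
        p_small = fl.kill_probability(0.1, 50.0, 5.0, tr)
        assert p_tall < p_small
        assert p_tall < 0.02  # mature stems essentially untouched at FI 0.1

    def test_monotone_in_intensity(self, species):
        tr = species["Dahurian larch"]
        fi = np.linspace(0, 1, 50)
        p = fl.kill_probability(fi, 600.0, 210.0, tr)
        assert (np.diff(p) >= -1e-12).all()

    def test_thicker_bark_protects(self, species):
        base = species["Dahurian larch"]
        thick = dataclasses.replace(base, bark_coef=2 * base.bark_coef)
        assert stem_kill_prob(0.5, 600.0, thick) < stem_kill_prob(0.5, 600.0, base)

    def test_higher_crown_base_protects(self):
        p_low = crown_kill_prob(0.5, 800.0, 100.0)
        p_high = crown_kill_prob(0.5, 800.0, 500.0)
        assert p_high < p_low

    def test_bark_thickness_proportional_to_height(self, species):
        tr = species["Dahurian larch"]
        assert bark_thickness_cm(1000.0, tr) == pytest.approx(1000.0 * tr.bark_coef)

    def test_resprouting_restarts_at_reduced_height(self, species):
        tr = dataclasses.replace(species["Dahurian larch"], resprout_prob=1.0)
        rng = np.random.default_rng(0)
        tree = Tree("Dahurian larch", 1.0, 1.0, height=1000.0, crown_base=350.0)
        alive, resprouted = fl.tree_fire_mortality(tree, 1.0, tr, rng)
        assert alive and resprouted
        assert tree.height == pytest.approx(100.0)


class TestSeedPools:
    def _setup(self, species, scape, cone_seeds=0):
        pop = fl.TreePopulation(list(species))
        pop.add(0, scape.width_m / 2, scape.height_m / 2, height=900.0,
                crown_base=300.0, age=80)
        pop.cone_seeds[0] = cone_seeds
        return pop

    def test_ground_seeds_erased_by_any_positive_intensity(self, species,
                                                           small_landscape):
        scape = small_landscape
        scape.ground_seeds.clear()
        grid = scape.seed_grid("Dahurian larch")
        grid[:] = 0
        grid[10, 10] = 500
        pop = self._setup(species, scape)
        ev = fl.fixed_fire_event(0, 0.0001, scape)
        fl.burn_seed_pools(scape, pop, ev, np.random.default_rng(1))
        assert grid.sum() == 0

    def test_zero_intensity_leaves_pools_unchanged(self, species, small_landscape):
        scape = small_landscape
        scape.ground_seeds.clear()
        grid = scape.seed_grid("Dahurian larch")
        grid[5, 5] = 200
        pop = self._setup(species, scape, cone_seeds=300)
        ev = fl.fixed_fire_event(0, 0.0, scape)
        ground_lost, cone_lost = fl.burn_seed_pools(
            scape, pop, ev, np.random.default_rng(1))
        assert ground_lost == 0 and cone_lost == 0
        assert grid[5, 5] == 200 and pop.cone_seeds[0] == 300

    def test_cone_destruction_is_binomial_in_intensity(self, species,
                                                       small_landscape):
        scape = small_landscape
        scape.ground_seeds.clear()
        pop = self._setup(species, scape, cone_seeds=10_000)
        ev = fl.fixed_fire_event(0, 0.5, scape)
        _, cone_lost = fl.burn_seed_pools(scape, pop, ev,
                                          np.random.default_rng(2))
        sigma = np.sqrt(10_000 * 0.5 * 0.5)
        assert abs(cone_lost - 5_000) < 3 * sigma


class TestBurnLitter:
    def test_full_removal_at_and_above_threshold(self):
        assert fl.burn_litter(13.0, 0.8) == 0.0
        assert fl.burn_litter(13.0, 1.0) == 0.0

    def test_zero_intensity_is_identity(self):
        assert fl.burn_litter(13.0, 0.0) == pytest.approx(13.0)

    def test_removal_monotone_in_intensity(self):
        fi = np.linspace(0, 1, 50)
        after = fl.burn_litter(13.0, fi)
        assert (np.diff(after) <= 1e-12).all()
        assert (after <= 13.0).all()


class TestStemFootprint:
    def test_small_tree_reads_containing_cell(self, small_landscape):
        ev = fl.fixed_fire_event(0, 0.7, small_landscape)
        fi = fl.stem_mean_intensity(ev, small_landscape,
                                    x=5.05, y=5.05, height_cm=150.0)
        assert fi[0] == pytest.approx(0.7)

    def test_tall_tree_on_cell_border_averages(self, small_landscape):
        ev = fl.fixed_fire_event(0, 0.4, small_landscape)
        # uniform field: averaging must return the same value
        fi = fl.stem_mean_intensity(ev, small_landscape,
                                    x=5.0, y=5.0, height_cm=1200.0)
        assert fi[0] == pytest.approx(0.4)


class TestApplyFire:
    def _stand(self, species, scape, n=60, height=900.0):
        rng = np.random.default_rng(3)
        pop = fl.TreePopulation(list(species))
        land_r, land_c = np.nonzero(scape.land_fine)
        pick = rng.choice(land_r.size, size=n, replace=False)
        res = scape.fine_res_m
        pop.add(0, (land_c[pick] + 0.5) * res, (land_r[pick] + 0.5) * res,
                height=height, crown_base=0.3 * height, age=80)
        return pop

    def test_zero_intensity_event_changes_nothing(self, species, small_landscape):
        scape = small_landscape
        pop = self._stand(species, scape)
        scape.ground_seeds.clear()
        scape.seed_grid("Dahurian larch")[3, 3] = 50
        litter_before = scape.litter_height.copy()
        ev = fl.fixed_fire_event(0, 0.0, scape)
        summary = fl.apply_fire(scape, pop, species, ev, np.random.default_rng(4))
        assert summary.total_killed == 0
        assert summary.ground_seeds_destroyed == 0
        assert summary.cone_seeds_destroyed == 0
        assert pop.n_alive == len(pop)
        np.testing.assert_array_equal(scape.litter_height, litter_before)

    def test_stand_replacing_fire_resets_live_trees(self, species, wet_landscape):
        pop = self._stand(species, wet_landscape)
        ev = fl.fixed_fire_event(0, 1.0, wet_landscape)
        summary = fl.apply_fire(wet_landscape, pop, species, ev,
                                np.random.default_rng(5))
        n_resprouted = sum(summary.resprouted.values())
        assert pop.n_alive == n_resprouted  # survivors are resprouts only
        assert wet_landscape.litter_height.max() == 0.0

    def test_accounting_identity(self, species, small_landscape):
        pop = self._stand(species, small_landscape, n=80, height=400.0)
        pre_live = pop.n_alive
        ev = fl.fixed_fire_event(0, 0.6, small_landscape)
        summary = fl.apply_fire(small_landscape, pop, species, ev,
                                np.random.default_rng(6))
        assert summary.total_killed == pre_live - pop.n_alive
        per_species = sum(summary.trees_killed.values())
        assert per_species == summary.total_killed

    def test_fire_never_increases_seeds_or_litter(self, species, small_landscape):
        scape = small_landscape
        pop = self._stand(species, scape)
        pop.cone_seeds[:] = 100
        scape.ground_seeds.clear()
        grid = scape.seed_grid("Dahurian larch")
        grid[::7, ::7] = 20
        ground_before = int(grid.sum())
        cones_before = int(pop.cone_seeds.sum())
        litter_before = scape.litter_height.copy()
        ev = fl.fixed_fire_event(0, 0.5, scape)
        fl.apply_fire(scape, pop, species, ev, np.random.default_rng(7))
        assert int(grid.sum()) <= ground_before
        assert int(pop.cone_seeds.sum()) <= cones_before
        assert (scape.litter_height <= litter_before + 1e-6).all()
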