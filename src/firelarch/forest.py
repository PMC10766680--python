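"""Individual-based annual forest demography and below-ground state.

A deliberately minimal demographic cycle for millennial runs: trees grow as
a function of growing-season temperature, a height-asymptote factor and
local competition; mature trees fill cones and shed seeds through an
isotropic Gaussian kernel; seeds germinate where the litter layer is thin
and the seasonal thaw (active layer) is deep enough for the species; trees
die from background risk, senescence, and competition.  The litter layer
regrows at 0.5 cm/yr with stochastic small-scale disturbances calibrated to
a ~13 cm long-run mean, and the active-layer depth relaxes toward a
Stefan-type equilibrium (proportional to the square root of the degree-day
thaw index) damped by litter insulation.

Scalar, per-tree forms of each rule are exposed for direct use and testing;
the :class:`TreePopulation` holds the same state as flat arrays and the
population-level drivers apply identical formulas vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count

import numpy as np
from scipy.spatial import cKDTree

from .landscape import Landscape
from .species import SpeciesTraits

__all__ = [
    "ForestParams", "LitterParams", "ActiveLayerParams", "Tree",
    "TreePopulation", "temp_suitability", "height_increment", "annual_growth",
    "competition_index", "competition_indices", "natural_mortality_prob",
    "natural_mortality", "update_litter", "update_active_layer",
    "calibrate_litter_disturbance", "produce_and_disperse", "establish",
]


# ---- parameters -----------------------------------------------------------

@dataclass(frozen=True)
class ForestParams:
    """Demography tunables shared across species."""

    crown_base_fraction: float = 0.35     # crown base rises toward this height fraction
    crown_rise_rate: float = 0.2          # yearly relaxation toward the target fraction
    competition_radius_m: float = 10.0    # neighborhood radius for competition
    competition_h_ref_cm: float = 1000.0  # height normalization of the kernel
    comp_mortality_coef: float = 0.03     # hazard per unit competition index
    senescence_fraction: float = 0.8      # age/max_age where senescence risk starts
    germination_base_rate: float = 0.02   # per-seed germination at zero litter
    litter_inhibition_per_cm: float = 0.177  # exp decay of germination with litter
    seed_release_fraction: float = 0.5    # cone seeds released per year
    ground_seed_survival: float = 0.5     # yearly survival of the ground seed bank
    seedling_height_cm: float = 1.0
    max_recruits_per_cell: float = 1      # one 0.2 m cell holds one recruit per year
    snag_delay_yr: int = 0                # years a dead tree is kept before removal


@dataclass(frozen=True)
class LitterParams:
    """Litter-layer regrowth and stochastic small-scale disturbance.

    With disturbances off, regrowth is exactly +0.5 cm/yr up to the cap.
    ``p_disturbance`` defaults to the analytically calibrated value for a
    13 cm long-run mean under U(0, 1) removal fractions (see
    :func:`calibrate_litter_disturbance`).
    """

    regrowth_cm_per_yr: float = 0.5
    cap_cm: float = 40.0
    p_disturbance: float = 2.0 / 27.0

    def stationary_mean_cm(self) -> float:
        """Stationary mean height ignoring the (rarely binding) cap."""
        q = self.p_disturbance * 0.5  # E[removed fraction] = 1/2
        return self.regrowth_cm_per_yr * (1.0 - q) / q


def calibrate_litter_disturbance(target_mean_cm: float = 13.0,
                                 regrowth_cm_per_yr: float = 0.5) -> float:
    """Disturbance probability giving a target stationary mean litter height.

    Balance of the per-cell process h' = (h + g) * (1 - F*B) with
    B ~ Bernoulli(p), F ~ U(0, 1):  m = (m + g)(1 - p/2), hence
    p = 2 g / (m + g).  For g = 0.5 and m = 13 this is 2/27.
    """
    g = regrowth_cm_per_yr
    return 2.0 * g / (target_mean_cm + g)


@dataclass(frozen=True)
class ActiveLayerParams:
    """Active-layer (seasonal thaw) equilibrium and relaxation.

    Equilibrium depth = stefan_coef * sqrt(thaw index) * exp(-k * litter).
    Defaults put the bare-ground equilibrium at c. 105 cm and the 13 cm
    litter equilibrium at c. 60 cm under a thaw index of ~1740 degC days
    (the stationary synthetic climate of the reference site).
    """

    stefan_coef: float = 2.517            # cm per sqrt(degC day)
    insulation_per_cm: float = 0.04303    # exp decay of depth with litter height
    efolding_yr: float = 5.0              # multi-year thermal memory


# ---- per-tree record ------------------------------------------------------

_tree_ids = count()


@dataclass
class Tree:
    """A single individual; used by the scalar rule functions and tests."""

    species: str
    x: float
    y: float
    height: float                 # cm
    crown_base: float = 0.0       # cm; no foliage below this height
    age: int = 0
    alive: bool = True
    cone_seeds: int = 0
    id: int = field(default_factory=lambda: next(_tree_ids))

    def __post_init__(self) -> None:
        if not (0.0 <= self.crown_base < self.height):
            raise ValueError("crown_base must satisfy 0 <= crown_base < height")


# ---- growth ---------------------------------------------------------------

def temp_suitability(t_growing_season: float, traits: SpeciesTraits):
    """Gaussian suitability of the growing-season mean temperature, in (0, 1]."""
    z = (np.asarray(t_growing_season, dtype=float) - traits.temp_optimum_c)
    out = np.exp(-z ** 2 / (2.0 * traits.temp_tolerance_c ** 2))
    return float(out) if out.ndim == 0 else out


def _size_factor(height, max_height_cm: float):
    """Height-asymptote factor: 1 below half the maximum, then linear to 0.

    Keeps the young-tree increment exactly growth_rate * suitability /
    (1 + competition) while bounding heights below the species maximum.
    """
    h = np.asarray(height, dtype=float)
    return np.clip(2.0 * (1.0 - h / max_height_cm), 0.0, 1.0)


def height_increment(height, traits: SpeciesTraits, t_growing_season,
                     competition) -> np.ndarray:
    """Annual height increment (cm): rate * suitability * size / (1 + CI)."""
    suit = temp_suitability(t_growing_season, traits)
    dh = (traits.growth_rate_cm_per_yr * suit
          * _size_factor(height, traits.max_height_cm)
          / (1.0 + np.asarray(competition, dtype=float)))
    return dh


def annual_growth(tree: Tree, climate_year, competition: float,
                  traits: SpeciesTraits,
                  params: ForestParams | None = None) -> float:
    """Grow one tree for a year; returns and applies the updated height.

    ``climate_year`` is the 12-month climate frame of the year; growth
    responds to the mean temperature of months above 0 degC.  The crown
    base rises toward ``crown_base_fraction`` of the height.
    """
    from .climate import growing_season_mean

    params = params or ForestParams()
    if not tree.alive:
        raise ValueError("cannot grow a dead tree")
    t_gs = growing_season_mean(climate_year["t_mon"].to_numpy())
    tree.height += float(height_increment(tree.height, traits, t_gs, competition))
    target = params.crown_base_fraction * tree.height
    tree.crown_base += params.crown_rise_rate * max(0.0, target - tree.crown_base)
    return tree.height


# ---- competition ----------------------------------------------------------

def competition_index(target_height: float, neighbor_heights, distances,
                      params: ForestParams | None = None) -> float:
    """Shading index from taller-or-equal neighbors within the radius.

    Sum over neighbors with h_j >= h_i of (h_j / h_ref) * (1 - d / R): each
    term increases with neighbor height and decreases with distance; an
    isolated tree scores zero.
    """
    params = params or ForestParams()
    h = np.asarray(neighbor_heights, dtype=float)
    d = np.asarray(distances, dtype=float)
    sel = (h >= target_height) & (d < params.competition_radius_m)
    kern = (h[sel] / params.competition_h_ref_cm) \
        * (1.0 - d[sel] / params.competition_radius_m)
    return float(kern.sum())


def competition_indices(x, y, height, params: ForestParams | None = None) -> np.ndarray:
    """Competition index for every tree, via a KD-tree neighbor query."""
    params = params or ForestParams()
    n = len(x)
    ci = np.zeros(n)
    if n < 2:
        return ci
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.competition_radius_m, output_type="ndarray")
    if len(pairs) == 0:
        return ci
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.hypot(x[i] - x[j], y[i] - y[j])
    w = 1.0 - d / params.competition_radius_m
    h = np.asarray(height, dtype=float)
    # j shades i where h_j >= h_i, and vice versa (ties shade both ways)
    shade_i = h[j] >= h[i]
    shade_j = h[i] >= h[j]
    np.add.at(ci, i[shade_i], (h[j][shade_i] / params.competition_h_ref_cm) * w[shade_i])
    np.add.at(ci, j[shade_j], (h[i][shade_j] / params.competition_h_ref_cm) * w[shade_j])
    return ci


# ---- mortality ------------------------------------------------------------

def natural_mortality_prob(age, traits: SpeciesTraits, competition,
                           params: ForestParams | None = None):
    """Annual death probability: background, senescence, and competition.

    Independent hazards combined as 1 - (1-bg)(1-p_age)(1-p_comp).  The
    senescence term is zero below ``senescence_fraction * max_age`` and
    reaches 1 at max_age (certain death beyond it); a young, uncrowded tree
    dies exactly at the background rate.
    """
    params = params or ForestParams()
    age = np.asarray(age, dtype=float)
    s = params.senescence_fraction * traits.max_age_yr
    p_age = np.clip((age - s) / (traits.max_age_yr - s), 0.0, 1.0) ** 2
    p_age = np.where(age >= traits.max_age_yr, 1.0, p_age)
    p_comp = 1.0 - np.exp(-params.comp_mortality_coef
                          * np.asarray(competition, dtype=float))
    p = 1.0 - (1.0 - traits.background_mortality) * (1.0 - p_age) * (1.0 - p_comp)
    return float(p) if p.ndim == 0 else p


def natural_mortality(tree: Tree, competition: float, rng: np.random.Generator,
                      traits: SpeciesTraits,
                      params: ForestParams | None = None) -> bool:
    """Draw this year's survival for one tree; updates and returns ``alive``."""
    p = natural_mortality_prob(tree.age, traits, competition, params)
    if rng.random() < p:
        tree.alive = False
    return tree.alive


# ---- litter and active layer ----------------------------------------------

def update_litter(litter: np.ndarray, land_mask: np.ndarray,
                  rng: np.random.Generator | None,
                  params: LitterParams | None = None,
                  foliage_supply: float | np.ndarray = 1.0) -> np.ndarray:
    """One year of litter regrowth and stochastic small-scale disturbance.

    Growth is ``regrowth * clip(foliage_supply, 0, 1)`` cm (default full
    supply), capped at ``cap_cm``; each land cell is independently
    disturbed with probability ``p_disturbance``, losing a U(0, 1) fraction
    of its height.  Pass ``rng=None`` to disable disturbances (regrowth is
    then exactly +0.5 cm/yr up to the cap).  Water cells stay at zero.
    """
    params = params or LitterParams()
    supply = np.clip(np.asarray(foliage_supply, dtype=float), 0.0, 1.0)
    out = litter + params.regrowth_cm_per_yr * supply * land_mask
    if rng is not None and params.p_disturbance > 0.0:
        hit = (rng.random(out.shape) < params.p_disturbance) & land_mask
        n_hit = int(hit.sum())
        if n_hit:
            keep = 1.0 - rng.random(n_hit)
            out = np.asarray(out, dtype=np.float64)
            out[hit] *= keep
    out = np.clip(out, 0.0, params.cap_cm)
    return np.where(land_mask, out, 0.0).astype(np.float32)


def active_layer_equilibrium(thaw_index: float, litter,
                             params: ActiveLayerParams | None = None):
    """Equilibrium thaw depth (cm) for a degree-day index and litter height."""
    params = params or ActiveLayerParams()
    litter = np.asarray(litter, dtype=float)
    depth = (params.stefan_coef * np.sqrt(max(thaw_index, 0.0))
             * np.exp(-params.insulation_per_cm * litter))
    return float(depth) if depth.ndim == 0 else depth


def update_active_layer(active_layer: np.ndarray, thaw_index: float,
                        litter: np.ndarray, land_mask: np.ndarray,
                        params: ActiveLayerParams | None = None) -> np.ndarray:
    """Relax thaw depth toward its equilibrium with multi-year memory.

    depth += (equilibrium - depth) / efolding_yr.  Removing litter strictly
    increases the equilibrium, so post-fire cells deepen over the following
    years rather than instantaneously.
    """
    params = params or ActiveLayerParams()
    eq = active_layer_equilibrium(thaw_index, litter, params)
    out = active_layer + (eq - active_layer) / max(params.efolding_yr, 1.0)
    return np.where(land_mask, out, 0.0).astype(np.float32)


# ---- population container ---------------------------------------------------

class TreePopulation:
    """Flat-array tree population (structure of arrays) for vectorized steps.

    Positions are immutable for a tree's lifetime; dead trees are retained
    for ``snag_delay_yr`` years and then dropped.  Counts change only
    through recruitment (+) and mortality or fire (-).
    """

    def __init__(self, species_names: list[str]) -> None:
        self.species_names = list(species_names)
        self.species = np.zeros(0, dtype=np.int16)
        self.x = np.zeros(0)
        self.y = np.zeros(0)
        self.height = np.zeros(0)
        self.crown_base = np.zeros(0)
        self.age = np.zeros(0, dtype=np.int32)
        self.alive = np.zeros(0, dtype=bool)
        self.cone_seeds = np.zeros(0, dtype=np.int64)
        self.years_dead = np.zeros(0, dtype=np.int16)
        self.ids = np.zeros(0, dtype=np.int64)
        self._next_id = 0

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def add(self, species_idx, x, y, height, crown_base=None, age=0) -> None:
        n = np.size(x)
        if n == 0:
            return
        species_idx = np.broadcast_to(np.asarray(species_idx, dtype=np.int16), (n,))
        height = np.broadcast_to(np.asarray(height, dtype=float), (n,))
        if crown_base is None:
            crown_base = np.zeros(n)
        self.species = np.concatenate([self.species, species_idx])
        self.x = np.concatenate([self.x, np.broadcast_to(np.asarray(x, float), (n,))])
        self.y = np.concatenate([self.y, np.broadcast_to(np.asarray(y, float), (n,))])
        self.height = np.concatenate([self.height, height])
        self.crown_base = np.concatenate(
            [self.crown_base, np.broadcast_to(np.asarray(crown_base, float), (n,))])
        self.age = np.concatenate(
            [self.age, np.broadcast_to(np.asarray(age, np.int32), (n,))])
        self.alive = np.concatenate([self.alive, np.ones(n, dtype=bool)])
        self.cone_seeds = np.concatenate([self.cone_seeds, np.zeros(n, dtype=np.int64)])
        self.years_dead = np.concatenate([self.years_dead, np.zeros(n, dtype=np.int16)])
        self.ids = np.concatenate(
            [self.ids, np.arange(self._next_id, self._next_id + n, dtype=np.int64)])
        self._next_id += n

    def kill(self, mask: np.ndarray) -> None:
        """Mark trees dead (idempotent; dead trees never revive)."""
        self.alive &= ~mask

    def sweep_dead(self, snag_delay_yr: int = 0) -> None:
        """Advance snag age and drop dead trees past the retention delay."""
        self.years_dead[~self.alive] += 1
        keep = self.alive | (self.years_dead <= snag_delay_yr)
        if not keep.all():
            for name in ("species", "x", "y", "height", "crown_base", "age",
                         "alive", "cone_seeds", "years_dead", "ids"):
                setattr(self, name, getattr(self, name)[keep])

    def live_view(self) -> np.ndarray:
        return np.flatnonzero(self.alive)


# ---- seed production, dispersal, establishment ------------------------------

def produce_and_disperse(pop: TreePopulation, landscape: Landscape,
                         species: dict[str, SpeciesTraits],
                         rng: np.random.Generator,
                         params: ForestParams | None = None) -> int:
    """Fill cones of mature trees and release seeds through a Gaussian kernel.

    Mature live trees (height >= species maturity) add their annual seed
    production to their cones; a binomial fraction of each cone is released
    and placed isotropically around the parent (sd = species dispersal sd),
    truncated to the area.  Seeds landing on water are discarded.  Returns
    the number of seeds deposited on land.
    """
    params = params or ForestParams()
    deposited = 0
    for s_idx, name in enumerate(pop.species_names):
        tr = species[name]
        sel = np.flatnonzero(pop.alive & (pop.species == s_idx)
                             & (pop.height >= tr.maturity_height_cm))
        if sel.size == 0:
            continue
        pop.cone_seeds[sel] += int(round(tr.seeds_per_year))
        released = rng.binomial(pop.cone_seeds[sel], params.seed_release_fraction)
        pop.cone_seeds[sel] -= released
        total = int(released.sum())
        if total == 0:
            continue
        px = np.repeat(pop.x[sel], released)
        py = np.repeat(pop.y[sel], released)
        sx = px + rng.normal(0.0, tr.dispersal_sd_m, size=total)
        sy = py + rng.normal(0.0, tr.dispersal_sd_m, size=total)
        inside = (sx >= 0) & (sx < landscape.width_m) \
            & (sy >= 0) & (sy < landscape.height_m)
        sx, sy = sx[inside], sy[inside]
        if sx.size == 0:
            continue
        on_land = ~landscape.is_water_xy(sx, sy)
        sx, sy = sx[on_land], sy[on_land]
        if sx.size == 0:
            continue
        r, c = landscape.fine_index(sx, sy)
        np.add.at(landscape.seed_grid(name), (r, c), 1)
        deposited += sx.size
    return deposited


def germination_probability(litter_cm, params: ForestParams | None = None):
    """Per-seed germination probability: base_rate * exp(-k * litter)."""
    params = params or ForestParams()
    out = params.germination_base_rate * np.exp(
        -params.litter_inhibition_per_cm * np.asarray(litter_cm, dtype=float))
    return float(out) if out.ndim == 0 else out


def establish(landscape: Landscape, species: dict[str, SpeciesTraits],
              rng: np.random.Generator,
              params: ForestParams | None = None) -> dict[str, np.ndarray]:
    """Germinate ground seeds into seedlings, gated by thaw depth and litter.

    Per fine cell and species: germination is binomial over the cell's seed
    bank with probability base_rate * exp(-k * litter) where the active
    layer meets the species threshold, zero otherwise.  Germinated seeds
    are consumed; recruitment is capped at one seedling per cell per year
    (a 0.2 m cell holds one germinant).  Seed banks decay by the yearly
    ground-seed survival.  Returns per-species (x, y) recruit positions.
    """
    params = params or ForestParams()
    res = landscape.fine_res_m
    recruits: dict[str, np.ndarray] = {}
    for name, grid in landscape.ground_seeds.items():
        tr = species[name]
        rows, cols = np.nonzero(grid)
        if rows.size == 0:
            continue
        bank = grid[rows, cols]
        al_ok = landscape.active_layer_depth[rows, cols] >= tr.min_active_layer_cm
        germ = np.zeros(rows.size, dtype=np.int64)
        if al_ok.any():
            p = germination_probability(
                landscape.litter_height[rows[al_ok], cols[al_ok]], params)
            germ[al_ok] = rng.binomial(bank[al_ok], p)
        remaining = bank - germ
        # seed bank decay (after germination)
        if params.ground_seed_survival < 1.0:
            remaining = rng.binomial(remaining, params.ground_seed_survival)
        grid[rows, cols] = remaining.astype(np.int32)
        newly = germ > 0
        if newly.any():
            rr, cc = rows[newly], cols[newly]
            jitter = rng.uniform(-0.45 * res, 0.45 * res, size=(rr.size, 2))
            xs = (cc + 0.5) * res + jitter[:, 0]
            ys = (rr + 0.5) * res + jitter[:, 1]
            recruits[name] = np.column_stack([xs, ys])
    return recruits
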