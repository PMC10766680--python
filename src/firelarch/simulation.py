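"""Annual simulation loop, scenario experiments, and run outputs.

Each simulated year runs, in order: fire-weather rating, the (at most one)
fire of the year, demography (growth, seed production and dispersal,
establishment, natural mortality), litter and active-layer updates, and
the annual metrics.  Fire comes before demography so that post-fire
establishment can respond within the same year.

Three fire modes exist: ``climate_driven`` (ignition drawn against the
calibrated FPR_ann; extent and intensity follow the fire-weather rating
and the local TWI), ``fixed`` (whole-area fires at a prescribed intensity
every ``fixed_fri`` years, skipping TWI mediation so the scenario
intensity is exactly as labeled), and ``off``.

Randomness is split into named substreams (ignition, placement, demography,
disturbance, litter) spawned from one master seed, so that toggling fire
does not perturb the demographic draws: a fire-on run in which no ignition
happens is bit-identical to the fire-off run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .climate import (SyntheticClimateParams, generate_synthetic_climate,
                      growing_season_mean, read_climate_csv, thaw_index,
                      validate_climate)
from .fire_engine import FireParams, fixed_fire_event, draw_ignition, make_fire_event
from .fire_impacts import ImpactParams, apply_fire
from .fire_weather import FprCalibration, FprModel, annual_rating, calibrate
from .forest import (ActiveLayerParams, ForestParams, LitterParams,
                     TreePopulation, competition_indices, establish,
                     height_increment, natural_mortality_prob,
                     produce_and_disperse, temp_suitability, update_active_layer,
                     update_litter)
from .landscape import Landscape, generate_synthetic_landscape, write_ascii_grid
from .species import SpeciesTraits, default_species

__all__ = ["RunConfig", "SimulationState", "RunResult", "run_simulation",
           "run_annual_cycle", "run_experiment_suite", "compute_fri_stats",
           "load_config", "write_outputs"]

FIRE_MODES = ("climate_driven", "off", "fixed")
FIXED_FRIS = (10, 50, 100, 200, 300)
FIXED_FIS = (0.1, 0.5, 1.0)


@dataclass
class RunConfig:
    """Configuration of one simulation run."""

    n_years: int = 1000
    spinup_years: int = 0              # fire-free lead-in before the run proper
    seed: int = 0
    fire_mode: str = "climate_driven"
    fixed_fri: int | None = None       # years, fixed mode only
    fixed_fi: float | None = None      # intensity, fixed mode only
    t_factor: float = 1.0              # sensitivity perturbations, in {0.95, 1, 1.05}
    p_factor: float = 1.0
    fire_mortality_factor: float = 1.0
    snapshot_interval_yr: int = 100
    # landscape: synthetic fractal by default (desk scale, 99 x 99 m)
    landscape_n_coarse: int = 11
    landscape_coarse_res_m: float = 9.0
    landscape_water_fraction: float = 0.0
    climate_csv: str | None = None     # external forcing; synthetic if None
    climate_params: SyntheticClimateParams = field(default_factory=SyntheticClimateParams)
    initial_density_per_ha: dict[str, float] = field(default_factory=lambda: {
        "Dahurian larch": 300.0, "Cajander larch": 20.0, "Siberian larch": 60.0,
        "Siberian spruce": 20.0, "Scots pine": 30.0, "Siberian pine": 20.0})
    initial_height_cm: float = 50.0
    label: str = "run"

    def __post_init__(self) -> None:
        if self.fire_mode not in FIRE_MODES:
            raise ValueError(f"fire_mode must be one of {FIRE_MODES}")
        if self.fire_mode == "fixed" and (self.fixed_fri is None or self.fixed_fi is None):
            raise ValueError("fixed fire mode requires fixed_fri and fixed_fi")
        for f in (self.t_factor, self.p_factor, self.fire_mortality_factor):
            if not 0.5 <= f <= 1.5:
                raise ValueError("perturbation factors must be near 1")


@dataclass
class SimulationState:
    """Mutable state of a running simulation."""

    landscape: Landscape
    pop: TreePopulation
    species: dict[str, SpeciesTraits]
    forest_params: ForestParams
    litter_params: LitterParams
    active_layer_params: ActiveLayerParams
    fire_params: FireParams
    impact_params: ImpactParams
    fpr_model: FprModel
    fpr_calibration: FprCalibration
    rngs: dict[str, np.random.Generator]
    year: int = 0


@dataclass
class RunResult:
    config: RunConfig
    annual: pd.DataFrame
    fires: pd.DataFrame
    snapshots: dict[int, dict[str, np.ndarray]]
    state: SimulationState


def make_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named independent substreams from one master seed."""
    names = ("ignition", "placement", "demography", "disturbance", "litter")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def initialize_state(config: RunConfig,
                     landscape: Landscape | None = None,
                     species: dict[str, SpeciesTraits] | None = None,
                     calibration_series: pd.DataFrame | None = None) -> SimulationState:
    """Build the initial state: landscape, planted juveniles, calibrated FPR.

    The FPR_ann scale is calibrated on ``calibration_series`` (default: a
    500-year synthetic series with the run's climate parameters) so the
    mean annual ignition probability hits the configured target.
    """
    rngs = make_rngs(config.seed)
    species = species or default_species()
    if landscape is None:
        landscape = generate_synthetic_landscape(
            n_coarse=config.landscape_n_coarse,
            coarse_res_m=config.landscape_coarse_res_m,
            water_fraction=config.landscape_water_fraction,
            seed=config.seed + 1_000_003)

    pop = TreePopulation(list(species))
    rng = rngs["demography"]
    area_ha = landscape.width_m * landscape.height_m / 1e4
    for s_idx, name in enumerate(pop.species_names):
        n = int(round(config.initial_density_per_ha.get(name, 0.0) * area_ha))
        if n == 0:
            continue
        xs, ys = [], []
        while len(xs) < n:  # rejection-sample land positions
            cx = rng.uniform(0.0, landscape.width_m, size=2 * n)
            cy = rng.uniform(0.0, landscape.height_m, size=2 * n)
            ok = ~landscape.is_water_xy(cx, cy)
            xs.extend(cx[ok][: n - len(xs)])
            ys.extend(cy[ok][: n - len(ys)])
            if not ok.any():
                break
        h = config.initial_height_cm
        pop.add(s_idx, np.array(xs), np.array(ys), height=h,
                crown_base=0.2 * h, age=5)

    fpr_model = FprModel()
    if calibration_series is None:
        calibration_series = generate_synthetic_climate(
            500, config.climate_params, seed=config.seed + 7)
    fpr_cal = calibrate(calibration_series, fpr_model, target_mean=0.03)

    return SimulationState(
        landscape=landscape, pop=pop, species=species,
        forest_params=ForestParams(), litter_params=LitterParams(),
        active_layer_params=ActiveLayerParams(), fire_params=FireParams(),
        impact_params=ImpactParams(), fpr_model=fpr_model,
        fpr_calibration=fpr_cal, rngs=rngs)


def _demography_step(state: SimulationState, t_gs: float) -> None:
    """Growth, seed production/dispersal, establishment, mortality; one year."""
    pop = state.pop
    fp = state.forest_params
    rng = state.rngs["demography"]
    live = pop.live_view()

    ci_live = np.zeros(live.size)
    if live.size:
        # one competition pass per year, shared by growth and mortality
        ci_live = competition_indices(pop.x[live], pop.y[live], pop.height[live], fp)
        for s_idx, name in enumerate(pop.species_names):
            mask = pop.species[live] == s_idx
            if mask.any():
                sel = live[mask]
                tr = state.species[name]
                pop.height[sel] += height_increment(
                    pop.height[sel], tr, t_gs, ci_live[mask])
        target = fp.crown_base_fraction * pop.height[live]
        pop.crown_base[live] += fp.crown_rise_rate * np.maximum(
            0.0, target - pop.crown_base[live])

    produce_and_disperse(pop, state.landscape, state.species, rng, fp)

    recruits = establish(state.landscape, state.species, rng, fp)
    for name, xy in recruits.items():
        s_idx = pop.species_index(name)
        pop.add(s_idx, xy[:, 0], xy[:, 1], height=fp.seedling_height_cm,
                crown_base=0.0, age=0)

    live = pop.live_view()
    if live.size:
        # recruits (appended last) enter at zero competition in their first year
        ci = np.zeros(live.size)
        ci[:ci_live.size] = ci_live
        p_death = np.zeros(live.size)
        for s_idx, name in enumerate(pop.species_names):
            sel = pop.species[live] == s_idx
            if sel.any():
                p_death[sel] = natural_mortality_prob(
                    pop.age[live][sel], state.species[name], ci[sel], fp)
        dead = rng.random(live.size) < p_death
        pop.alive[live[dead]] = False

    pop.age[pop.alive] += 1
    pop.sweep_dead(fp.snag_delay_yr)


def _annual_metrics(state: SimulationState, year: int, fpr_ann: float,
                    burned_cells: int) -> dict:
    pop = state.pop
    live = pop.live_view()
    h = pop.height[live]
    record: dict[str, float] = {
        "year": year, "fpr_ann": fpr_ann, "burned_cells": burned_cells,
        "stem_count": int(np.count_nonzero(h >= 130.0)),
        "seedling_count": int(np.count_nonzero(h <= 40.0)),
        "n_trees": int(live.size),
    }
    mature = h > 200.0
    record["mean_height_mature"] = float(h[mature].mean()) if mature.any() else np.nan
    n_dec = n_ever = 0
    for s_idx, name in enumerate(pop.species_names):
        sel = pop.species[live] == s_idx
        stems = int(np.count_nonzero(sel & (h >= 130.0)))
        record[f"stem_count_{name.replace(' ', '_')}"] = stems
        if state.species[name].deciduous:
            n_dec += int(sel.sum())
        else:
            n_ever += int(sel.sum())
    record["evergreen_deciduous_ratio"] = n_ever / n_dec if n_dec else np.nan
    land = state.landscape.land_fine
    record["mean_litter_cm"] = float(state.landscape.litter_height[land].mean())
    record["mean_active_layer_cm"] = float(
        state.landscape.active_layer_depth[land].mean())
    return record


def run_annual_cycle(state: SimulationState, climate_year: pd.DataFrame,
                     config: RunConfig, year_index: int) -> tuple[dict, dict | None]:
    """One simulated year; returns (annual record, fire record or None).

    ``year_index`` counts years since the end of spin-up; fixed-mode fires
    burn in years congruent to 0 modulo the fixed return interval.
    """
    t_mon = climate_year["t_mon"].to_numpy() * config.t_factor
    p_mon = climate_year["p_mon"].to_numpy() * config.p_factor
    months = pd.DataFrame({"year": climate_year["year"].to_numpy(),
                           "month": climate_year["month"].to_numpy(),
                           "t_mon": t_mon, "p_mon": p_mon})
    rating = annual_rating(months, state.fpr_model, state.fpr_calibration)
    fpr_ann = rating.fpr_ann
    year = int(months["year"].iloc[0])

    fire_record = None
    burned = 0
    if config.fire_mode == "climate_driven":
        ignited = draw_ignition(fpr_ann, state.rngs["ignition"])
        if ignited:
            event = make_fire_event(year, fpr_ann, state.landscape,
                                    state.rngs["placement"], state.fire_params)
            summary = apply_fire(state.landscape, state.pop, state.species,
                                 event, state.rngs["disturbance"],
                                 state.impact_params, state.fire_params,
                                 state.forest_params,
                                 mortality_factor=config.fire_mortality_factor)
            burned = event.burned_cell_count
            fire_record = _fire_row(event, summary)
    elif config.fire_mode == "fixed":
        if year_index >= 0 and year_index % int(config.fixed_fri) == 0:
            event = fixed_fire_event(year, float(config.fixed_fi), state.landscape)
            summary = apply_fire(state.landscape, state.pop, state.species,
                                 event, state.rngs["disturbance"],
                                 state.impact_params, state.fire_params,
                                 state.forest_params,
                                 mortality_factor=config.fire_mortality_factor)
            burned = event.burned_cell_count
            fire_record = _fire_row(event, summary)

    t_gs = growing_season_mean(t_mon)
    _demography_step(state, t_gs)

    land = state.landscape.land_fine
    state.landscape.litter_height = update_litter(
        state.landscape.litter_height, land, state.rngs["litter"],
        state.litter_params)
    state.landscape.active_layer_depth = update_active_layer(
        state.landscape.active_layer_depth, thaw_index(t_mon),
        state.landscape.litter_height, land, state.active_layer_params)

    record = _annual_metrics(state, year, fpr_ann, burned)
    state.year = year
    return record, fire_record


def _fire_row(event, summary) -> dict:
    return {
        "year": event.year, "center_x": event.center_x, "center_y": event.center_y,
        "diameter_m": event.diameter, "fpr_ann": event.fpr_ann_at_event,
        "burned_cells": event.burned_cell_count,
        "trees_killed": summary.total_killed,
        "cone_seeds_destroyed": summary.cone_seeds_destroyed,
        "ground_seeds_destroyed": summary.ground_seeds_destroyed,
        "litter_removed_mean_cm": summary.litter_removed_mean_cm,
    }


def spatial_snapshot(state: SimulationState) -> dict[str, np.ndarray]:
    """Per-coarse-cell means of litter and active layer, plus tree counts."""
    scape = state.landscape
    k = scape.fine_per_coarse
    n = scape.n_coarse

    def coarse_mean(fine: np.ndarray) -> np.ndarray:
        return fine.reshape(n, k, n, k).mean(axis=(1, 3))

    out = {"mean_litter_cm": coarse_mean(scape.litter_height.astype(float)),
           "mean_active_layer_cm": coarse_mean(scape.active_layer_depth.astype(float))}
    pop = state.pop
    live = pop.live_view()
    r, c = scape.coarse_index(pop.x[live], pop.y[live])
    stems = pop.height[live] >= 130.0  # abundance is reported at stem level
    for s_idx, name in enumerate(pop.species_names):
        counts = np.zeros((n, n))
        sel = (pop.species[live] == s_idx) & stems
        np.add.at(counts, (r[sel], c[sel]), 1.0)
        out[f"abundance_{name.replace(' ', '_')}"] = counts
    return out


def run_simulation(config: RunConfig,
                   landscape: Landscape | None = None,
                   species: dict[str, SpeciesTraits] | None = None,
                   climate: pd.DataFrame | None = None,
                   progress: bool = False) -> RunResult:
    """Run spin-up plus the configured years and collect outputs.

    Climate is read from ``config.climate_csv`` if set, else generated
    synthetically (stationary by default) long enough to cover spin-up and
    run; an explicit ``climate`` frame overrides both.
    """
    total_years = config.spinup_years + config.n_years
    if climate is None:
        if config.climate_csv:
            climate = read_climate_csv(config.climate_csv)
        else:
            climate = generate_synthetic_climate(
                total_years, config.climate_params, seed=config.seed + 13)
    climate = validate_climate(climate)
    years = climate["year"].unique()
    if len(years) < total_years:
        raise ValueError(f"climate series has {len(years)} years; "
                         f"run needs {total_years}")

    state = initialize_state(config, landscape, species)
    annual_rows, fire_rows = [], []
    snapshots: dict[int, dict[str, np.ndarray]] = {}
    year_groups = dict(tuple(climate.groupby("year")))

    for i, year in enumerate(years[:total_years]):
        year_index = i - config.spinup_years
        in_spinup = year_index < 0
        cfg = replace(config, fire_mode="off") if in_spinup else config
        record, fire = run_annual_cycle(state, year_groups[year], cfg, year_index)
        record["spinup"] = in_spinup
        annual_rows.append(record)
        if fire is not None:
            fire_rows.append(fire)
        if progress and (i + 1) % 100 == 0:
            import sys
            print(f"[{config.label}] year {i + 1}/{total_years}, "
                  f"trees={record['n_trees']}", file=sys.stderr)
        if (not in_spinup and config.snapshot_interval_yr
                and year_index % config.snapshot_interval_yr == 0):
            snapshots[int(year)] = spatial_snapshot(state)

    annual = pd.DataFrame(annual_rows)
    fires = pd.DataFrame(fire_rows, columns=[
        "year", "center_x", "center_y", "diameter_m", "fpr_ann", "burned_cells",
        "trees_killed", "cone_seeds_destroyed", "ground_seeds_destroyed",
        "litter_removed_mean_cm"])
    return RunResult(config=config, annual=annual, fires=fires,
                     snapshots=snapshots, state=state)


def compute_fri_stats(fire_years, window: tuple[int, int] | None = None
                      ) -> tuple[float, float]:
    """Mean and population sd of inter-fire intervals inside ``window``.

    Returns (nan, nan) with a warning when fewer than two fires fall in
    the window.
    """
    years = np.sort(np.asarray(fire_years, dtype=float))
    if window is not None:
        lo, hi = window
        years = years[(years >= lo) & (years <= hi)]
    if years.size < 2:
        warnings.warn("fewer than 2 fires in window; FRI undefined")
        return float("nan"), float("nan")
    intervals = np.diff(years)
    return float(intervals.mean()), float(intervals.std())


# ---- experiment suite ------------------------------------------------------

def build_experiment_configs(base: RunConfig) -> list[RunConfig]:
    """The factorial scenario set: reference with and without fire, six
    one-at-a-time +/-5% sensitivity runs, and the 15 fixed FRI x FI runs
    (23 runs in total)."""
    configs = [replace(base, fire_mode="climate_driven", label="fire_on"),
               replace(base, fire_mode="off", label="fire_off")]
    for factor in (0.95, 1.05):
        tag = f"{int(round(factor * 100))}"
        configs.append(replace(base, fire_mode="climate_driven",
                               t_factor=factor, label=f"sens_t_{tag}"))
        configs.append(replace(base, fire_mode="climate_driven",
                               p_factor=factor, label=f"sens_p_{tag}"))
        configs.append(replace(base, fire_mode="climate_driven",
                               fire_mortality_factor=factor,
                               label=f"sens_mort_{tag}"))
    for fri in FIXED_FRIS:
        for fi in FIXED_FIS:
            configs.append(replace(base, fire_mode="fixed", fixed_fri=fri,
                                   fixed_fi=fi, label=f"fri{fri}_fi{fi}"))
    return configs


def run_experiment_suite(base: RunConfig, out_dir, overwrite: bool = False,
                         progress: bool = False) -> list[Path]:
    """Run the 23-scenario suite sequentially; one subdirectory per run."""
    out_dir = Path(out_dir)
    paths = []
    for config in build_experiment_configs(base):
        run_dir = out_dir / config.label
        if run_dir.exists() and not overwrite:
            raise FileExistsError(f"{run_dir} exists (pass overwrite=True)")
        result = run_simulation(config, progress=progress)
        write_outputs(result, run_dir)
        paths.append(run_dir)
    return paths


def write_outputs(result: RunResult, run_dir) -> None:
    """Write annual.csv, fires.csv, snapshot layers (ESRI ASCII), manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    result.annual.to_csv(run_dir / "annual.csv", index=False)
    result.fires.to_csv(run_dir / "fires.csv", index=False)
    res = result.state.landscape.coarse_res_m
    for year, layers in result.snapshots.items():
        for layer, arr in layers.items():
            write_ascii_grid(arr, run_dir / f"snapshot_{year}_{layer}.asc",
                             cellsize=res)
    manifest = asdict(result.config)
    manifest["code_version"] = _version
    with open(run_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration (sections forcing, landscape, fire, run)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    forcing = raw.get("forcing", {})
    if "climate_csv" in forcing:
        kwargs["climate_csv"] = forcing["climate_csv"]
    if "synthetic" in forcing:
        kwargs["climate_params"] = SyntheticClimateParams(**forcing["synthetic"])
    scape = raw.get("landscape", {})
    for key, dest in (("n_coarse", "landscape_n_coarse"),
                      ("coarse_res_m", "landscape_coarse_res_m"),
                      ("water_fraction", "landscape_water_fraction")):
        if key in scape:
            kwargs[dest] = scape[key]
    fire = raw.get("fire", {})
    for key in ("fire_mode", "fixed_fri", "fixed_fi", "fire_mortality_factor"):
        if key in fire:
            kwargs[key] = fire[key]
    run = raw.get("run", {})
    for key in ("n_years", "spinup_years", "seed", "snapshot_interval_yr",
                "t_factor", "p_factor", "label"):
        if key in run:
            kwargs[key] = run[key]
    return RunConfig(**kwargs)
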