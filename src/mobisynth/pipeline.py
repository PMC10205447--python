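"""End-to-end orchestration of the synthesis pipeline.

Each stage is a pure function from the previous stage's outputs (plus the
fixture world and a seed) to its own outputs; the CLI persists each stage
as CSV so stages are independently re-runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activities, attributes, eval_io, fixtures, location_mode, popsynth
from .config import Config


@dataclass
class PipelineResult:
    world: fixtures.World
    persons: pd.DataFrame
    households: pd.DataFrame
    schedules: list[activities.Schedule]
    durations: pd.DataFrame
    activity_table: pd.DataFrame
    gravity: location_mode.GravityFit
    tour_modes: pd.Series
    home_buildings: pd.Series
    warnings: list[str] = field(default_factory=list)


def stage_fixtures(config: Config, seed: int,
                   n_trips_per_cell: int = 500) -> fixtures.World:
    world_cfg = config.world
    world_cfg.seed = int(seed)
    return fixtures.generate_full_world(world_cfg, n_trips_per_cell=n_trips_per_cell)


def stage_synthesize(world: fixtures.World, config: Config, seed: int):
    return popsynth.synthesize_population(world, config.popsynth, seed)


def stage_attributes(world: fixtures.World, persons: pd.DataFrame,
                     households: pd.DataFrame, config: Config, seed: int):
    return attributes.assign_advanced_attributes(
        persons, households, world.survey_persons, world, config.attributes, seed)


def stage_activities(world: fixtures.World, persons: pd.DataFrame,
                     config: Config, seed: int) -> activities.ActivityStageResult:
    return activities.generate_activity_schedules(
        persons, world.survey_persons, world.survey_diary, config.activities, seed)


def fit_world_gravity(world: fixtures.World) -> location_mode.GravityFit:
    """Gravity fit on the fixture's survey trips with standard masses."""
    masses = {p: world.zone_attraction_mass(p) for p in ("W", "S", "O")}
    return location_mode.fit_gravity(world.survey_trips, world.zones, masses,
                                     world.distance_matrix_km())


def stage_locate(world: fixtures.World, persons: pd.DataFrame,
                 households: pd.DataFrame,
                 act: activities.ActivityStageResult, config: Config,
                 seed: int):
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 51]))
    d = world.distance_matrix_km()
    vz = location_mode.build_virtual_zones(world.zones, world.grid)
    home = location_mode.assign_home_buildings(households, vz, world.buildings,
                                               config.location, rng)
    gravity = fit_world_gravity(world)
    od_probs = location_mode.build_od_probabilities(world.zones, d, od=world.od,
                                                    gravity=gravity)
    mode_model = location_mode.train_mode_model(world.survey_persons,
                                                world.survey_diary)
    hh_cars = households.set_index("HId")["n_cars"]
    tour_modes = location_mode.assign_modes(
        persons, act.schedules, mode_model, hh_cars, rng,
        walk_substitution_prob=config.location.walk_substitution_prob)
    located = location_mode.assign_zones_and_buildings(
        persons, act.schedules, tour_modes, od_probs, world.buildings, home, d, rng)
    return located, gravity, tour_modes, home


def run_all(config: Config, seed: int,
            n_trips_per_cell: int = 500) -> PipelineResult:
    """Run every stage on a freshly generated toy world."""
    world = stage_fixtures(config, seed, n_trips_per_cell)
    persons, households, warns = stage_synthesize(world, config, seed)
    persons, households = stage_attributes(world, persons, households, config, seed)
    act = stage_activities(world, persons, config, seed)
    located, gravity, tour_modes, home = stage_locate(
        world, persons, households, act, config, seed)
    return PipelineResult(
        world=world, persons=persons, households=households,
        schedules=act.schedules, durations=act.durations,
        activity_table=located.table, gravity=gravity, tour_modes=tour_modes,
        home_buildings=home, warnings=warns + located.warnings)


def evaluate(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """The standard evaluation set: marginal diffs, duration JS, distances."""
    report = eval_io.marginal_diff_report(result.persons, result.world.zone_margins)
    summary = eval_io.marginal_summary(report)
    js = duration_js_distances(result)
    dist = eval_io.trip_distance_distributions(result.activity_table)
    return {"marginal_report": report, "marginal_summary": summary,
            "duration_js": js, "trip_distances": dist}


def duration_js_distances(result: PipelineResult,
                          bins=None) -> pd.DataFrame:
    """JS distance between generated and survey duration distributions,
    per activity type, on shared 1 h bins."""
    if bins is None:
        bins = np.arange(0.0, 25.0, 1.0)
    feats = activities.diary_features(result.world.survey_persons,
                                      result.world.survey_diary)
    rows = []
    for p in ("H", "W", "S", "O"):
        gen = result.durations.loc[result.durations[f"t_{p}"] > 0, f"t_{p}"]
        ref = feats.loc[feats["participation"].str.contains(p), f"t_{p}"]
        if len(gen) == 0 or len(ref) == 0:
            continue
        pv = eval_io.histogram_distribution(gen, bins)
        qv = eval_io.histogram_distribution(ref, bins)
        rows.append({"activity_type": p, "js_distance": eval_io.js_distance(pv, qv),
                     "n_generated": int(len(gen)), "n_survey": int(len(ref))})
    return pd.DataFrame(rows)
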