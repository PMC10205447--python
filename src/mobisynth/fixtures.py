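"""Self-consistent toy region generator.

Produces every input the pipeline consumes — zone-level marginals,
municipal cross-tabulations, a population grid, a building register, a
travel-survey with activity diaries, and OD matrices — from known
ground-truth behavioural parameters, so each downstream stage can be tested
(including parameter recovery) without any external data.

Geometry is a rectangular tiling: each municipality is one row of zones and
each zone is a run of whole grid cells, so zone x grid intersections
("virtual zones") are exact by construction.  All aggregate tables are
mutually consistent by construction: municipal cross-tabs are sums of the
per-zone joint draws, and grid-cell populations partition zone populations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .config import BehaviourParams, WorldConfig, DurationSpec
from .errors import ConfigurationError, DataError
from . import vocab
from .vocab import AGE_BANDS, GENDERS, MARITAL, MODES, INCOME_CLASSES

# Relative plausibility of each 5-year age band (normalized at use).
_AGE_PYRAMID = np.array(
    [0.055, 0.057, 0.055, 0.053, 0.060, 0.065, 0.066, 0.063, 0.061, 0.062,
     0.063, 0.060, 0.055, 0.052, 0.048, 0.040, 0.030, 0.018, 0.008, 0.003]
)

_CANONICAL_SEQUENCES: dict[str, list[tuple[list[str], float]]] = {
    "H": [(["H"], 1.0)],
    "HW": [(["H", "W", "H"], 1.0)],
    "HS": [(["H", "S", "H"], 1.0)],
    "HO": [(["H", "O", "H"], 1.0)],
    "HOW": [(["H", "W", "O", "H"], 0.6), (["H", "O", "W", "H"], 0.2),
            (["H", "W", "O", "W", "H"], 0.2)],
    "HOS": [(["H", "S", "O", "H"], 0.7), (["H", "O", "S", "H"], 0.3)],
    "HSW": [(["H", "W", "S", "H"], 0.5), (["H", "S", "W", "H"], 0.5)],
    "HOSW": [(["H", "W", "S", "O", "H"], 0.5), (["H", "S", "W", "O", "H"], 0.5)],
}


def _prob_from_table(age: float, table: list[tuple[int, int, float]]) -> float:
    for lo, hi, p in table:
        if lo <= age <= hi:
            return p
    return 0.0


def civil_status_probs(band_label: str) -> np.ndarray:
    """P(civil status | age band) over (age<18, couple, single)."""
    lo, hi = vocab.age_band_bounds(band_label)
    if hi < 18:
        return np.array([1.0, 0.0, 0.0])
    if lo < 18:  # band straddles the age-18 boundary (15-19)
        under = (18 - lo) / (hi - lo + 1)
        return np.array([under, 0.10 * (1 - under), 0.90 * (1 - under)])
    mid = (lo + hi) / 2
    if mid < 25:
        couple = 0.20
    elif mid < 35:
        couple = 0.45
    elif mid < 65:
        couple = 0.60
    elif mid < 80:
        couple = 0.55
    else:
        couple = 0.35
    return np.array([0.0, couple, 1 - couple])


def _adult_mid_age(band_label: str) -> float:
    lo, hi = vocab.age_band_bounds(band_label)
    lo = max(lo, 18)
    return (lo + hi) / 2


def _minor_mid_age(band_label: str) -> float:
    lo, hi = vocab.age_band_bounds(band_label)
    hi = min(hi, 17)
    return (lo + hi) / 2


@dataclass
class World:
    """In-memory toy region: all tables the pipeline stages read."""

    zones: pd.DataFrame            # zone_id, municipality_id, extent, counts
    zone_margins: pd.DataFrame     # zone_id, gender, age_group, count
    crosstabs: pd.DataFrame        # municipality_id, gender, age_group, civil_status, count
    municipal_income: pd.DataFrame  # municipality_id, income_class, count
    municipal_children: pd.DataFrame  # municipality_id, household_type, count
    grid: pd.DataFrame             # cell_id, zone_id, x_min, y_min, size, population
    buildings: pd.DataFrame        # building_id, usage_type, x, y, footprint_area, zone_id
    behaviour: BehaviourParams
    survey_persons: pd.DataFrame | None = None
    survey_diary: pd.DataFrame | None = None
    survey_trips: pd.DataFrame | None = None
    od: pd.DataFrame | None = None

    def zone_ids(self) -> list[str]:
        return list(self.zones["zone_id"])

    def centroids(self) -> pd.DataFrame:
        return self.zones.set_index("zone_id")[["centroid_x", "centroid_y"]]

    def distance_matrix_km(self) -> pd.DataFrame:
        """Pairwise straight-line zone-centroid distances in km."""
        c = self.centroids()
        if c.isna().any().any():
            missing = c.index[c.isna().any(axis=1)].tolist()
            raise DataError(f"zones without centroids: {missing}")
        xy = c.to_numpy()
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)) / 1000.0
        return pd.DataFrame(d, index=c.index, columns=c.index)

    def zone_attraction_mass(self, purpose: str) -> pd.Series:
        """Gravity attraction mass per zone: population for W/O trips,
        total school footprint area for S trips."""
        if purpose == "S":
            schools = self.buildings[self.buildings["usage_type"] == "school"]
            mass = schools.groupby("zone_id")["footprint_area"].sum()
            return mass.reindex(self.zone_ids(), fill_value=0.0)
        return self.zones.set_index("zone_id")["population"].astype(float)


def _integerize_vector(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Truncate-replicate-sample a non-negative vector to integers."""
    floors = np.floor(values).astype(int)
    remainder = int(round(values.sum())) - floors.sum()
    frac = values - np.floor(values)
    out = floors.copy()
    if remainder > 0 and frac.sum() > 0:
        p = frac / frac.sum()
        idx = rng.choice(len(values), size=remainder, replace=False, p=p)
        out[idx] += 1
    return out


def generate_world(config: WorldConfig) -> World:
    """Generate zones, cross-tabs, grid and buildings for the toy region."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    params = config.behaviour

    band_labels = [b[0] for b in AGE_BANDS]
    pyramid = _AGE_PYRAMID / _AGE_PYRAMID.sum()
    civil = np.stack([civil_status_probs(b) for b in band_labels])  # (20, 3)
    # joint cell probabilities over gender x band x civil
    joint_p = 0.5 * pyramid[None, :, None] * civil[None, :, :]
    joint_p = np.broadcast_to(joint_p, (2, len(band_labels), 3)).reshape(-1)
    joint_p = joint_p / joint_p.sum()

    zone_width = config.cells_per_zone * config.grid_cell_size
    cell = config.grid_cell_size
    lo, hi = config.persons_per_zone_range

    zone_rows, margin_rows, grid_rows, building_rows = [], [], [], []
    joint_by_zone: dict[str, np.ndarray] = {}
    building_id = 1
    for mi in range(config.n_municipalities):
        muni = f"M{mi:02d}"
        for zi in range(config.zones_per_municipality):
            zone = f"{muni}Z{zi:03d}"
            n = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(n, joint_p).reshape(2, len(band_labels), 3)
            joint_by_zone[zone] = counts

            for gi, g in enumerate(GENDERS):
                for bi, b in enumerate(band_labels):
                    margin_rows.append(
                        {"zone_id": zone, "gender": g, "age_group": b,
                         "count": int(counts[gi, bi].sum())}
                    )

            # household-type targets implied by the drawn civil statuses
            couple_m = int(counts[0, :, 1].sum())
            couple_f = int(counts[1, :, 1].sum())
            singles = int(counts[:, :, 2].sum())
            n_couple_hh = min(couple_m, couple_f)
            n_single_hh = int(round(0.85 * singles))
            leftover = (couple_m + couple_f - 2 * n_couple_hh) + (singles - n_single_hh)
            n_other_hh = int(np.ceil(leftover / 3)) if leftover else 0

            # expected employees / students / cars under the true behaviour
            exp_emp = exp_stu = exp_cars = 0.0
            for bi, b in enumerate(band_labels):
                adults = counts[:, bi, 1:].sum()
                minors = counts[:, bi, 0].sum()
                a_mid = _adult_mid_age(b)
                m_mid = _minor_mid_age(b)
                p_emp = _prob_from_table(a_mid, params.employment_prob_by_age)
                exp_emp += adults * p_emp
                exp_stu += adults * _prob_from_table(a_mid, params.studenthood_prob_by_age)
                exp_stu += minors * _prob_from_table(m_mid, params.studenthood_prob_by_age)
                car_w = np.array([0.0, 1.0, 2.0, 3.0])
                e_cars = p_emp * np.dot(params.car_probs_employed, car_w) + (
                    1 - p_emp) * np.dot(params.car_probs_not_employed, car_w)
                exp_cars += adults * e_cars

            x0 = zi * zone_width
            y0 = mi * cell
            zone_rows.append(
                {"zone_id": zone, "municipality_id": muni,
                 "x_min": x0, "y_min": y0, "x_max": x0 + zone_width, "y_max": y0 + cell,
                 "centroid_x": x0 + zone_width / 2, "centroid_y": y0 + cell / 2,
                 "population": n,
                 "n_households_single": n_single_hh,
                 "n_households_couple": n_couple_hh,
                 "n_households_other": n_other_hh,
                 "n_employees": int(round(exp_emp)),
                 "n_students": int(round(exp_stu)),
                 "n_cars": int(round(exp_cars))}
            )

            # grid cells tile the zone; their populations partition n exactly
            weights = rng.dirichlet(np.full(config.cells_per_zone, 2.0))
            cell_pops = _integerize_vector(weights * n, rng)
            for ci in range(config.cells_per_zone):
                grid_rows.append(
                    {"cell_id": f"{zone}C{ci}", "zone_id": zone,
                     "x_min": x0 + ci * cell, "y_min": y0, "size": cell,
                     "population": int(cell_pops[ci])}
                )

            area_logmean = {"detached_house": np.log(120.0), "apartment": np.log(800.0),
                            "workplace": np.log(600.0), "school": np.log(1500.0),
                            "other": np.log(400.0)}
            area_logsd = {"detached_house": 0.3, "apartment": 0.4, "workplace": 0.6,
                          "school": 0.3, "other": 0.5}
            for usage in vocab.BUILDING_USAGE_TYPES:
                n_b = int(config.building_density.get(usage, 0))
                for _ in range(n_b):
                    bx = round(float(rng.uniform(x0 + 5, x0 + zone_width - 5)), 1)
                    by = round(float(rng.uniform(y0 + 5, y0 + cell - 5)), 1)
                    area = round(float(rng.lognormal(area_logmean[usage], area_logsd[usage])), 1)
                    building_rows.append(
                        {"building_id": building_id, "usage_type": usage,
                         "x": bx, "y": by, "footprint_area": area, "zone_id": zone}
                    )
                    building_id += 1

    zones = pd.DataFrame(zone_rows)
    zone_margins = pd.DataFrame(margin_rows)

    # municipal cross-tab = exact sum of per-zone joint draws
    ct_rows = []
    for mi in range(config.n_municipalities):
        muni = f"M{mi:02d}"
        member = [z for z in joint_by_zone if z.startswith(muni)]
        total = np.sum([joint_by_zone[z] for z in member], axis=0)
        for gi, g in enumerate(GENDERS):
            for bi, b in enumerate(band_labels):
                for ci, c in enumerate(MARITAL):
                    ct_rows.append(
                        {"municipality_id": muni, "gender": g, "age_group": b,
                         "civil_status": c, "count": int(total[gi, bi, ci])}
                    )
    crosstabs = pd.DataFrame(ct_rows)

    # municipal income-class counts (expected under true behaviour, summing
    # exactly to the municipal population via largest remainder)
    inc_rows, child_rows = [], []
    for mi in range(config.n_municipalities):
        muni = f"M{mi:02d}"
        member = [z for z in joint_by_zone if z.startswith(muni)]
        total = np.sum([joint_by_zone[z] for z in member], axis=0)  # (2,20,3)
        pop = int(total.sum())
        expected = np.zeros(len(INCOME_CLASSES))
        minors_total = 0
        for bi, b in enumerate(band_labels):
            adults = total[:, bi, 1:].sum()
            minors = total[:, bi, 0].sum()
            minors_total += minors
            p_emp = _prob_from_table(_adult_mid_age(b), params.employment_prob_by_age)
            expected += adults * (
                p_emp * np.array(params.income_probs_employed)
                + (1 - p_emp) * np.array(params.income_probs_not_employed)
            )
            expected[0] += minors  # minors carry no personal income
        ints = np.floor(expected).astype(int)
        frac = expected - ints
        for _ in range(pop - ints.sum()):
            k = int(np.argmax(frac))
            ints[k] += 1
            frac[k] = -1
        for k, c in enumerate(INCOME_CLASSES):
            inc_rows.append({"municipality_id": muni, "income_class": c, "count": int(ints[k])})
        for htype, share in (("couple", 0.60), ("single", 0.25), ("other", 0.15)):
            child_rows.append({"municipality_id": muni, "household_type": htype,
                               "count": int(round(minors_total * share))})

    return World(
        zones=zones, zone_margins=zone_margins, crosstabs=crosstabs,
        municipal_income=pd.DataFrame(inc_rows),
        municipal_children=pd.DataFrame(child_rows),
        grid=pd.DataFrame(grid_rows), buildings=pd.DataFrame(building_rows),
        behaviour=params,
    )


def _sample_participation(emp: int, stud: int, params: BehaviourParams,
                          rng: np.random.Generator) -> str:
    dist = params.participation_probs[f"{emp},{stud}"]
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _truncnorm_sample(spec: DurationSpec, rng: np.random.Generator) -> float:
    a = (spec.lower - spec.mean) / spec.sd
    b = (spec.upper - spec.mean) / spec.sd
    return float(stats.truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, random_state=rng))


def _pick_sequence(subset: str, rng: np.random.Generator) -> list[str]:
    options = _CANONICAL_SEQUENCES[subset]
    probs = np.array([p for _, p in options])
    k = rng.choice(len(options), p=probs / probs.sum())
    return list(options[k][0])


def mode_choice_probs(distance_km: float, has_car: bool,
                      params: BehaviourParams) -> pd.Series:
    """Softmax mode-choice probabilities given trip distance and car access.

    Car (as driver) is unavailable to carless travellers.
    """
    utils = {}
    for mode in MODES:
        coef = params.mode_utility[mode]
        if mode == "Car" and not has_car:
            continue
        utils[mode] = coef["const"] + coef["per_km"] * distance_km + coef["car_coeff"] * has_car
    keys = sorted(utils)
    u = np.array([utils[k] for k in keys])
    e = np.exp(u - u.max())
    return pd.Series(e / e.sum(), index=keys)


def build_diary_rows(sequence: list[str], durations: dict[str, float],
                     travel_total: float, anchor_fraction: float) -> list[dict]:
    """Lay a condensed activity sequence onto the 3 AM-anchored day.

    The first/last entry is the single episode spanning 3 AM; it receives
    ``anchor_fraction`` of its instance duration after 3 AM.  Remaining
    instances of each type share that type's total duration equally, and
    the total travel time is split equally over the gaps.
    Returns rows with relative start/end hours in [0, 24].
    """
    if len(sequence) == 1:
        return [{"purpose": sequence[0], "start_rel": 0.0, "end_rel": 24.0}]
    if sequence[0] != sequence[-1]:
        raise DataError("sequence must start and end with the 3 AM-spanning type")
    # instance slots: first and last entries are one (anchor) instance
    inner = sequence[1:-1]
    n_instances = {t: 1 + inner.count(t) if t == sequence[0] else inner.count(t)
                   for t in set(sequence)}
    per_instance = {t: durations[t] / n_instances[t] for t in n_instances}
    n_trips = len(sequence) - 1
    gap = travel_total / n_trips
    d_anchor = per_instance[sequence[0]]
    f = anchor_fraction * d_anchor
    rows = [{"purpose": sequence[0], "start_rel": 0.0, "end_rel": f}]
    t = f
    for purpose in inner:
        t += gap
        rows.append({"purpose": purpose, "start_rel": t, "end_rel": t + per_instance[purpose]})
        t += per_instance[purpose]
    t += gap
    rows.append({"purpose": sequence[0], "start_rel": t, "end_rel": 24.0})
    return rows


def rel_to_clock(rel: float) -> float:
    """Convert hours-after-3AM to decimal clock hours (one decimal)."""
    return round((rel + 3.0) % 24.0, 1)


def generate_survey(world: World, n_respondents: int, params: BehaviourParams,
                    seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate survey respondents with 3 AM-anchored activity diaries.

    Returns (persons, diary) frames; diary times are decimal clock hours
    rounded to one decimal, with an empty access mode on the first episode.
    """
    if n_respondents < 1:
        raise ConfigurationError("n_respondents must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 12]))

    band_labels = [b[0] for b in AGE_BANDS]
    # survey covers ages 6-84
    weights = []
    for label in band_labels:
        lo, hi = vocab.age_band_bounds(label)
        overlap = max(0, min(hi, 84) - max(lo, 6) + 1)
        weights.append(_AGE_PYRAMID[band_labels.index(label)] * overlap / (hi - lo + 1))
    weights = np.array(weights)
    weights /= weights.sum()

    persons, diary = [], []
    for rid in range(1, n_respondents + 1):
        bi = rng.choice(len(band_labels), p=weights)
        lo, hi = vocab.age_band_bounds(band_labels[bi])
        age = int(rng.integers(max(lo, 6), min(hi, 84) + 1))
        gender = GENDERS[int(rng.integers(2))]
        if age < 18:
            civil = "age<18"
        else:
            p = civil_status_probs(band_labels[bi])[1:]
            civil = ["couple", "single"][rng.choice(2, p=p / p.sum())]
        emp = int(age >= vocab.MIN_EMPLOYMENT_AGE
                  and rng.random() < _prob_from_table(age, params.employment_prob_by_age))
        stud = int(rng.random() < _prob_from_table(age, params.studenthood_prob_by_age))
        income_p = params.income_probs_employed if emp else params.income_probs_not_employed
        income = INCOME_CLASSES[rng.choice(5, p=np.array(income_p))]
        car_p = (params.car_probs_employed if emp else params.car_probs_not_employed)
        n_cars = int(rng.choice(4, p=np.array(car_p))) if age >= 18 else 0
        hsize = 2 if civil == "couple" else 1
        hsize += int(rng.poisson(0.8))
        persons.append(
            {"respondent_id": rid, "age": age, "gender": gender, "civil_status": civil,
             "employment": emp, "studenthood": stud, "income_class": income,
             "n_cars": n_cars, "household_size": min(hsize, 6)}
        )

        subset = _sample_participation(emp, stud, params, rng)
        durations = {t: _truncnorm_sample(params.duration_distributions[t], rng)
                     for t in subset}
        sequence = _pick_sequence(subset, rng)
        n_trips = len(sequence) - 1
        if n_trips == 0:
            rows = build_diary_rows(sequence, {"H": 24.0}, 0.0, 0.5)
            mode = ""
        else:
            dist = float(np.clip(rng.lognormal(params.trip_distance_logmean,
                                               params.trip_distance_logsd), 0.3, 20.0))
            probs = mode_choice_probs(dist, n_cars > 0, params)
            mode = probs.index[rng.choice(len(probs), p=probs.to_numpy())]
            speed = params.mode_speed_kmh[mode]
            trip_time = dist / speed
            travel_total = n_trips * trip_time
            if travel_total > 3.8:  # keep within the top travel-time class
                travel_total = 3.8
            others = {t: d for t, d in durations.items() if t != "H"}
            t_home = 24.0 - travel_total - sum(others.values())
            h_min = params.duration_distributions["H"].lower
            if t_home < h_min:  # compress out-of-home time into the day
                scale = (24.0 - travel_total - h_min) / sum(others.values())
                others = {t: d * scale for t, d in others.items()}
                t_home = h_min
            durations = {"H": t_home, **others}
            anchor_fraction = float(np.clip(rng.normal(0.5, 0.15), 0.15, 0.85))
            rows = build_diary_rows(sequence, durations, travel_total, anchor_fraction)
        for k, row in enumerate(rows):
            diary.append(
                {"respondent_id": rid, "episode_id": k + 1, "purpose": row["purpose"],
                 "start_h": rel_to_clock(row["start_rel"]) if k > 0 else 3.0,
                 "end_h": rel_to_clock(row["end_rel"]) if k < len(rows) - 1 else 3.0,
                 "access_mode": mode if k > 0 else ""}
            )
    return pd.DataFrame(persons), pd.DataFrame(diary)


def gravity_probabilities(distances_km: pd.DataFrame, masses: pd.Series,
                          beta: float) -> pd.DataFrame:
    """Destination-choice probabilities P(j | i) ∝ mass_j · exp(-beta·d_ij)."""
    weight = masses.to_numpy()[None, :] * np.exp(-beta * distances_km.to_numpy())
    totals = weight.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DataError("a gravity origin row has zero total attraction")
    return pd.DataFrame(weight / totals, index=distances_km.index,
                        columns=distances_km.columns)


def generate_od_matrices(world: World, params: BehaviourParams, seed: int) -> pd.DataFrame:
    """Generate long-format OD flows per (origin, destination, mode, purpose).

    Flows follow the ground-truth gravity model: mass x exp(-beta·d), scaled
    so each (origin, mode, purpose) slice totals the configured amount.
    OD trip purposes are work/business/other/private (no school purpose).
    """
    d = world.distance_matrix_km()
    zone_ids = list(d.index)
    rows = []
    purpose_to_activity = {"work": "W", "business": "O", "other": "O", "private": "O"}
    mass = world.zone_attraction_mass("W")
    for purpose in vocab.OD_PURPOSES:
        act = purpose_to_activity[purpose]
        for mode in MODES:
            beta = params.gravity_beta[f"{act},{mode}"]
            probs = gravity_probabilities(d, mass, beta)
            for i, origin in enumerate(zone_ids):
                flow = probs.iloc[i].to_numpy() * 1000.0
                for j, dest in enumerate(zone_ids):
                    rows.append({"origin": origin, "destination": dest,
                                 "mode": mode, "purpose": purpose,
                                 "flow": round(float(flow[j]), 6)})
    return pd.DataFrame(rows)


def generate_trips(world: World, params: BehaviourParams, n_per_cell: int, seed: int,
                   purposes: tuple[str, ...] = ("W", "S", "O"),
                   modes: tuple[str, ...] = tuple(MODES)) -> pd.DataFrame:
    """Sample individual trips from the ground-truth gravity model.

    One batch of ``n_per_cell`` trips per (purpose, mode): origins drawn
    proportionally to zone population, destinations from the gravity
    distribution with the true deterrence rate.  Used as the survey-trip
    input to the gravity fit (parameter recovery) and OD fallbacks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    d = world.distance_matrix_km()
    zone_ids = list(d.index)
    pop = world.zones.set_index("zone_id")["population"].reindex(zone_ids).to_numpy(float)
    pop_p = pop / pop.sum()
    rows = []
    for purpose in purposes:
        masses = world.zone_attraction_mass(purpose).reindex(zone_ids)
        for mode in modes:
            beta = params.gravity_beta[f"{purpose},{mode}"]
            probs = gravity_probabilities(d, masses, beta).to_numpy()
            origins = rng.choice(len(zone_ids), size=n_per_cell, p=pop_p)
            for oi in origins:
                j = rng.choice(len(zone_ids), p=probs[oi])
                rows.append({"origin": zone_ids[oi], "destination": zone_ids[j],
                             "purpose": purpose, "mode": mode,
                             "distance_km": round(float(d.iloc[oi, j]), 6)})
    return pd.DataFrame(rows)


def generate_full_world(config: WorldConfig, n_trips_per_cell: int = 500) -> World:
    """Generate the complete fixture set: region, survey, OD matrices, trips."""
    world = generate_world(config)
    persons, diary = generate_survey(world, config.survey_size, config.behaviour,
                                     config.seed)
    world.survey_persons = persons
    world.survey_diary = diary
    world.od = generate_od_matrices(world, config.behaviour, config.seed)
    world.survey_trips = generate_trips(world, config.behaviour, n_trips_per_cell,
                                        config.seed)
    return world


# ---------------------------------------------------------------------------
# CSV round trip

_FILES = {
    "zones": "zones.csv",
    "zone_margins": "zone_margins.csv",
    "crosstabs": "crosstabs.csv",
    "municipal_income": "municipal_income.csv",
    "municipal_children": "municipal_children.csv",
    "grid": "grid.csv",
    "buildings": "buildings.csv",
    "survey_persons": "survey_persons.csv",
    "survey_diary": "survey_diary.csv",
    "survey_trips": "survey_trips.csv",
    "od": "od.csv",
}


def write_world(world: World, out_dir: str | Path) -> None:
    """Write every fixture table as UTF-8 CSV plus the ground-truth YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        df = getattr(world, attr)
        if df is not None:
            df.to_csv(out / fname, index=False)
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(_params_to_plain(world.behaviour), fh, sort_keys=True)


def _params_to_plain(params: BehaviourParams) -> dict:
    data = asdict(params)
    data["employment_prob_by_age"] = [list(t) for t in data["employment_prob_by_age"]]
    data["studenthood_prob_by_age"] = [list(t) for t in data["studenthood_prob_by_age"]]
    return data


def read_world(in_dir: str | Path) -> World:
    """Read a fixture directory written by :func:`write_world`."""
    src = Path(in_dir)
    frames = {}
    for attr, fname in _FILES.items():
        path = src / fname
        if path.exists():
            frames[attr] = pd.read_csv(path, keep_default_na=False,
                                       na_values=[], dtype={"access_mode": str}
                                       if attr == "survey_diary" else None)
        else:
            frames[attr] = None
    required = ["zones", "zone_margins", "crosstabs", "municipal_income",
                "municipal_children", "grid", "buildings"]
    for attr in required:
        if frames[attr] is None:
            raise DataError(f"fixture directory {src} is missing {_FILES[attr]}")
    with open(src / "ground_truth.yaml") as fh:
        raw = yaml.safe_load(fh)
    durations = {k: DurationSpec(**v) for k, v in raw.pop("duration_distributions").items()}
    emp = [tuple(t) for t in raw.pop("employment_prob_by_age")]
    stu = [tuple(t) for t in raw.pop("studenthood_prob_by_age")]
    behaviour = BehaviourParams(duration_distributions=durations,
                                employment_prob_by_age=emp,
                                studenthood_prob_by_age=stu, **raw)
    return World(behaviour=behaviour, **{k: frames[k] for k in _FILES})
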