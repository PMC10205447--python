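"""Stage 3: location and mode assignment.

Places households into residential buildings through virtual zones (zone x
grid-cell intersections), builds origin-destination probability matrices
from supplied OD flows with a gravity-model fallback, assigns a main tour
mode per agent (car driving requires a household car), couples destination
distance to travel time by within-stratum quantile matching, and places
every activity in a concrete building.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .activities import Schedule
from .config import LocationConfig
from .errors import DataError, FeasibilityError, FitError
from .fixtures import gravity_probabilities, rel_to_clock
from . import vocab
from .vocab import MODES, RESIDENTIAL_USAGE


# ---------------------------------------------------------------------------
# virtual zones and home buildings

def build_virtual_zones(zones: pd.DataFrame, grid: pd.DataFrame) -> pd.DataFrame:
    """One virtual zone per non-empty zone x grid-cell intersection.

    In the rectangular toy geometry every grid cell lies in exactly one
    zone, so the intersection is the cell itself; weights are the cell's
    share of the zone's grid population (uniform if the zone's grid total
    is zero).
    """
    rows = []
    for zone_id, g in grid.groupby("zone_id"):
        total = g["population"].sum()
        for _, cell in g.iterrows():
            weight = (cell["population"] / total) if total > 0 else 1.0 / len(g)
            rows.append({"vz_id": f"{zone_id}|{cell['cell_id']}",
                         "zone_id": zone_id, "cell_id": cell["cell_id"],
                         "x_min": cell["x_min"], "y_min": cell["y_min"],
                         "size": cell["size"], "population_weight": weight})
    vz = pd.DataFrame(rows)
    missing = set(zones["zone_id"]) - set(vz["zone_id"])
    if missing:
        raise DataError(f"zones without grid cells: {sorted(missing)}")
    return vz


def detached_probability(size: int, config: LocationConfig) -> float:
    """P(detached house | household size): logistic, increasing in size."""
    z = config.detached_intercept + config.detached_slope * float(size)
    return 1.0 / (1.0 + np.exp(-z))


def assign_home_buildings(households: pd.DataFrame, virtual_zones: pd.DataFrame,
                          buildings: pd.DataFrame, config: LocationConfig,
                          rng: np.random.Generator) -> pd.Series:
    """Home building per household (indexed by HId).

    Household -> virtual zone by population weight; building type drawn
    from the size-dependent detached/apartment model; concrete building
    uniform among that type within the virtual zone, falling back to the
    parent zone when the cell has none.
    """
    res = buildings[buildings["usage_type"].isin(RESIDENTIAL_USAGE)]
    by_zone_type: dict[tuple[str, str], pd.DataFrame] = {
        (z, u): g for (z, u), g in res.groupby(["zone_id", "usage_type"])
    }
    zones_with_res = set(res["zone_id"])
    missing = set(households["zone_id"]) - zones_with_res
    if missing:
        raise FeasibilityError(
            f"zones without residential buildings: {sorted(missing)}"
        )
    # pre-index buildings by virtual zone
    vz_by_zone = {z: g for z, g in virtual_zones.groupby("zone_id")}
    vz_members: dict[str, dict[str, pd.DataFrame]] = {}
    for vz_id, zone_id, x0, y0, size in virtual_zones[
            ["vz_id", "zone_id", "x_min", "y_min", "size"]].itertuples(index=False):
        inside = res[(res["zone_id"] == zone_id)
                     & (res["x"] >= x0) & (res["x"] < x0 + size)
                     & (res["y"] >= y0) & (res["y"] < y0 + size)]
        vz_members[vz_id] = {u: g for u, g in inside.groupby("usage_type")}

    out = {}
    for hid, zone_id, size in households[["HId", "zone_id", "size"]].itertuples(index=False):
        vz = vz_by_zone[zone_id]
        k = rng.choice(len(vz), p=vz["population_weight"].to_numpy()
                       / vz["population_weight"].sum())
        vz_id = vz["vz_id"].iloc[k]
        p_det = detached_probability(int(size), config)
        usage = "detached_house" if rng.random() < p_det else "apartment"
        pool = vz_members[vz_id].get(usage)
        if pool is None or len(pool) == 0:
            pool = by_zone_type.get((zone_id, usage))
        if pool is None or len(pool) == 0:
            other = "apartment" if usage == "detached_house" else "detached_house"
            pool = by_zone_type.get((zone_id, other))
        if pool is None or len(pool) == 0:
            raise FeasibilityError(f"zone {zone_id} has no residential building")
        out[int(hid)] = int(pool["building_id"].iloc[rng.integers(len(pool))])
    return pd.Series(out, name="building_id")


# ---------------------------------------------------------------------------
# gravity model

@dataclass
class GravityFit:
    """Fitted deterrence rates per (purpose, mode) with diagnostics."""

    beta: dict[tuple[str, str], float]
    masses: dict[str, pd.Series]          # attraction mass per purpose
    residual: dict[tuple[str, str], float]  # |model mean dist - observed|


def _model_mean_distance(beta: float, d: np.ndarray, masses: np.ndarray,
                         origin_weights: np.ndarray) -> float:
    w = masses[None, :] * np.exp(-beta * d)
    p = w / w.sum(axis=1, keepdims=True)
    return float((origin_weights[:, None] * p * d).sum() / origin_weights.sum())


def fit_gravity(trips: pd.DataFrame, zones: pd.DataFrame,
                masses: dict[str, pd.Series], distances_km: pd.DataFrame,
                min_trips: int = 20) -> GravityFit:
    """Fit the deterrence rate beta per (purpose, mode) from observed trips.

    P(j | i) ∝ mass_j · exp(-beta · d_ij); beta solves the moment condition
    that the model's mean trip distance (weighted by the observed origin
    mix) equals the observed mean, by monotone 1-D root finding.
    """
    zone_ids = list(distances_km.index)
    d = distances_km.to_numpy(float)
    betas, residuals = {}, {}
    for (purpose, mode), g in trips.groupby(["purpose", "mode"]):
        if len(g) < min_trips:
            raise DataError(
                f"only {len(g)} trips for ({purpose}, {mode}); need >= {min_trips}"
            )
        mass = masses[purpose].reindex(zone_ids).to_numpy(float)
        origin_counts = g["origin"].value_counts().reindex(zone_ids, fill_value=0)
        ow = origin_counts.to_numpy(float)
        if "distance_km" in g.columns:
            obs = float(g["distance_km"].mean())
        else:
            lookup = {z: i for i, z in enumerate(zone_ids)}
            obs = float(np.mean([d[lookup[o], lookup[dd]]
                                 for o, dd in zip(g["origin"], g["destination"])]))
        lo, hi = 1e-5, 50.0
        f_lo = _model_mean_distance(lo, d, mass, ow) - obs
        f_hi = _model_mean_distance(hi, d, mass, ow) - obs
        if f_lo * f_hi > 0:
            raise FitError(
                f"({purpose}, {mode}): observed mean distance {obs:.3f} km is outside "
                f"the model's range [{_model_mean_distance(hi, d, mass, ow):.3f}, "
                f"{_model_mean_distance(lo, d, mass, ow):.3f}] km; beta not bracketable"
            )
        beta = brentq(lambda b: _model_mean_distance(b, d, mass, ow) - obs, lo, hi,
                      xtol=1e-8)
        betas[(purpose, mode)] = float(beta)
        residuals[(purpose, mode)] = abs(_model_mean_distance(beta, d, mass, ow) - obs)
    return GravityFit(beta=betas, masses=dict(masses), residual=residuals)


# ---------------------------------------------------------------------------
# OD probabilities

OD_PURPOSE_TO_ACTIVITY = {"work": "W", "business": "O", "other": "O", "private": "O"}


@dataclass
class ODProbability:
    """P(destination zone | origin zone, activity purpose, mode)."""

    zone_ids: list[str]
    probs: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def get(self, origin: str, purpose: str, mode: str) -> np.ndarray:
        key = (origin, purpose, mode)
        if key not in self.probs:
            raise DataError(f"no OD probabilities for {key}")
        return self.probs[key]


def build_od_probabilities(zones: pd.DataFrame, distances_km: pd.DataFrame,
                           od: pd.DataFrame | None = None,
                           gravity: GravityFit | None = None) -> ODProbability:
    """Row-normalised destination distributions per (origin, purpose, mode).

    Supplied OD flows take precedence; the gravity fit fills the gaps.  OD
    trip purposes map {work -> W} and {business, other, private -> O};
    school (S) destinations always come from the gravity model over school
    attraction masses, since supplied OD matrices carry no school purpose.
    """
    zone_ids = list(distances_km.index)
    out = ODProbability(zone_ids=zone_ids)
    if od is not None and len(od):
        lookup = {z: i for i, z in enumerate(zone_ids)}
        od = od.copy()
        od["activity"] = od["purpose"].map(OD_PURPOSE_TO_ACTIVITY)
        if od["activity"].isna().any():
            bad = sorted(od.loc[od["activity"].isna(), "purpose"].unique())
            raise DataError(f"unknown OD trip purposes: {bad}")
        grouped = od.groupby(["origin", "activity", "mode", "destination"])["flow"].sum()
        for (origin, act, mode), g in grouped.groupby(level=[0, 1, 2]):
            vec = np.zeros(len(zone_ids))
            for (_, _, _, dest), flow in g.items():
                vec[lookup[dest]] = flow
            total = vec.sum()
            if total <= 0:
                raise DataError(
                    f"all-zero OD flow row for origin={origin}, purpose={act}, mode={mode}"
                )
            out.probs[(origin, act, mode)] = vec / total
    if gravity is not None:
        for (purpose, mode), beta in gravity.beta.items():
            mass = gravity.masses[purpose].reindex(zone_ids)
            probs = gravity_probabilities(distances_km, mass, beta)
            for i, origin in enumerate(zone_ids):
                key = (origin, purpose, mode)
                if key not in out.probs:  # supplied OD takes precedence
                    out.probs[key] = probs.iloc[i].to_numpy()
    return out


# ---------------------------------------------------------------------------
# mode assignment

def assign_modes(persons: pd.DataFrame, schedules: list[Schedule],
                 mode_model, household_cars: pd.Series,
                 rng: np.random.Generator,
                 walk_substitution_prob: float = 0.0) -> pd.Series:
    """One main tour mode per agent, respecting car availability.

    The choice model (trained on survey main modes) is conditioned on
    socio-demographics; the Car (driver) probability is zeroed for agents
    in carless households before sampling.  Per-trip modes equal the tour
    mode unless the optional walk substitution fires (handled at trip
    level by the caller).
    """
    with_trips = [s.pid for s in schedules if s.n_trips > 0]
    sub = persons.set_index("PId").loc[with_trips].copy()
    carless = (sub["HId"].map(household_cars).fillna(0) == 0).to_numpy()
    sub["has_car"] = (~carless).astype(int)
    P = mode_model.predict(sub.reset_index())
    cats = mode_model.choice_set
    if "Car" in cats:
        # driving requires a household car and an adult driver
        car_col = cats.index("Car")
        no_drive = carless | (sub["age"].to_numpy() < 18)
        P[no_drive, car_col] = 0.0
        P = P / P.sum(axis=1, keepdims=True)
    u = rng.random(len(sub))
    cdf = np.cumsum(P, axis=1)
    draw = (u[:, None] > cdf[:, :-1]).sum(axis=1)
    modes = pd.Series([cats[k] for k in draw], index=with_trips, name="mode")
    if walk_substitution_prob > 0:
        swap = rng.random(len(modes)) < walk_substitution_prob
        modes[swap] = "Walking"
    return modes


def train_mode_model(survey_persons: pd.DataFrame, survey_diary: pd.DataFrame):
    """Fit the tour-mode choice model on the survey's access modes."""
    from .attributes import train_choice_model
    main_mode = (survey_diary[survey_diary["access_mode"] != ""]
                 .groupby("respondent_id")["access_mode"]
                 .agg(lambda s: s.mode().iloc[0]))
    frame = survey_persons.merge(main_mode.rename("main_mode"), on="respondent_id")
    frame["has_car"] = (frame["n_cars"] > 0).astype(int)
    return train_choice_model(
        frame, ["age", "gender", "employment", "studenthood", "has_car"],
        "main_mode", choice_set=MODES)


# ---------------------------------------------------------------------------
# zone and building assignment

@dataclass
class LocatedActivityTable:
    table: pd.DataFrame
    warnings: list[str]


def assign_zones_and_buildings(persons: pd.DataFrame, schedules: list[Schedule],
                               tour_modes: pd.Series, od_probs: ODProbability,
                               buildings: pd.DataFrame, home_buildings: pd.Series,
                               distances_km: pd.DataFrame,
                               rng: np.random.Generator) -> LocatedActivityTable:
    """Complete every schedule with zones, buildings and coordinates.

    Destination zones realise the travel-time/distance rank coupling: for
    each trip, destinations are ordered by increasing distance from the
    origin zone and the inverse CDF of the destination distribution is
    evaluated at the agent's travel-time quantile among all trips of the
    same mode this run.  Consecutive activities chain (the origin of a
    trip is the previous activity's zone); home episodes reuse the
    household's building.
    """
    warnings: list[str] = []
    zone_ids = list(distances_km.index)
    zindex = {z: i for i, z in enumerate(zone_ids)}
    dmat = distances_km.to_numpy(float)

    b_by_id = buildings.set_index("building_id")
    by_zone_usage: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (z, u), g in buildings.groupby(["zone_id", "usage_type"]):
        areas = g["footprint_area"].to_numpy(float)
        by_zone_usage[(z, u)] = (g["building_id"].to_numpy(), areas / areas.sum())
    zones_with_usage: dict[str, list[str]] = {}
    for (z, u) in by_zone_usage:
        zones_with_usage.setdefault(u, []).append(z)

    person_by_pid = persons.set_index("PId")

    # travel-time quantiles among all same-mode trips in this run
    trip_records = []  # (schedule index, trip index, mode, travel time)
    for si, s in enumerate(schedules):
        if s.n_trips == 0:
            continue
        mode = tour_modes.get(s.pid)
        gap = s.travel_total / s.n_trips
        for ti in range(s.n_trips):
            trip_records.append((si, ti, mode, gap))
    tt_by_mode: dict[str, np.ndarray] = {}
    trips_df = pd.DataFrame(trip_records, columns=["si", "ti", "mode", "tt"])
    quantile = np.empty(len(trips_df))
    for mode, g in trips_df.groupby("mode"):
        ranks = g["tt"].rank(method="average").to_numpy()
        quantile[g.index.to_numpy()] = ranks / len(g)
    trips_df["q"] = quantile
    q_lookup = {(r.si, r.ti): r.q for r in trips_df.itertuples()}

    rows = []
    for si, s in enumerate(schedules):
        pid = s.pid
        prow = person_by_pid.loc[pid]
        home_b = int(home_buildings[int(prow["HId"])])
        home_zone = str(b_by_id.at[home_b, "zone_id"])
        mode = tour_modes.get(pid, "")
        current_zone = home_zone
        ep_locs = []
        for ei, ep in enumerate(s.episodes):
            purpose = ep["purpose"]
            if purpose == "H":
                bid, zone = home_b, str(b_by_id.at[home_b, "zone_id"])
            elif ei == len(s.episodes) - 1 and purpose == s.episodes[0]["purpose"]:
                # closing half of the anchor episode: same place as the opening
                bid, zone = ep_locs[0]
            else:
                q = q_lookup[(si, ei - 1)] if ei > 0 else 0.5
                dest_probs = od_probs.get(current_zone, purpose, mode)
                oi = zindex[current_zone]
                order = np.argsort(dmat[oi], kind="stable")
                cdf = np.cumsum(dest_probs[order])
                cdf = cdf / cdf[-1]
                k = int(np.searchsorted(cdf, q - 1e-12, side="left"))
                k = min(k, len(order) - 1)
                zone = zone_ids[order[k]]
                usage = vocab.PURPOSE_TO_USAGE[purpose]
                key = (zone, usage)
                if key not in by_zone_usage:
                    candidates = zones_with_usage.get(usage, [])
                    if not candidates:
                        raise FeasibilityError(f"no building of usage {usage!r} anywhere")
                    cz = min(candidates, key=lambda z: dmat[zindex[zone], zindex[z]])
                    warnings.append(
                        f"PId {pid}: no {usage} building in {zone}, using {cz}"
                    )
                    zone, key = cz, (cz, usage)
                bids, probs = by_zone_usage[key]
                bid = int(bids[rng.choice(len(bids), p=probs)])
            ep_locs.append((bid, zone))
            current_zone = zone
            rows.append(
                {"PId": pid, "activity_id": ei + 1,
                 "purpose": vocab.PURPOSE_NAMES[purpose],
                 "start_h": 3.0 if ei == 0 else rel_to_clock(ep["start_rel"]),
                 "end_h": 3.0 if ei == len(s.episodes) - 1 else rel_to_clock(ep["end_rel"]),
                 "mode": "" if ei == 0 else mode,
                 "building_id": bid,
                 "building_type": vocab.BUILDING_TYPE_NAMES[b_by_id.at[bid, "usage_type"]],
                 "x": round(float(b_by_id.at[bid, "x"]), 1),
                 "y": round(float(b_by_id.at[bid, "y"]), 1),
                 "zone_id": zone}
            )
    return LocatedActivityTable(table=pd.DataFrame(rows), warnings=warnings)
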