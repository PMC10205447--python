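"""Configuration objects for the toy-region generator and the pipeline.

A single YAML file drives every stage; :func:`load_config` merges it over
the defaults and :func:`dump_config` writes the resolved copy next to the
outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class DurationSpec:
    """Truncated-normal daily duration for one activity type (hours)."""

    mean: float
    sd: float
    lower: float
    upper: float


@dataclass
class BehaviourParams:
    """Ground-truth behavioural model behind the toy survey and OD flows.

    These parameters generate the fixture data and are persisted alongside
    it so that downstream fits (gravity deterrence, choice models) can be
    checked against a known truth.
    """

    # P(activity participation set | employment, studenthood); keys are
    # "emp,stud" flag pairs, values map sorted purpose strings to probability.
    participation_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "1,0": {"HW": 0.35, "HOW": 0.40, "HO": 0.15, "H": 0.10},
            "0,1": {"HS": 0.40, "HOS": 0.35, "HO": 0.15, "H": 0.10},
            "1,1": {"HSW": 0.30, "HOSW": 0.25, "HW": 0.15, "HS": 0.15, "HO": 0.10, "H": 0.05},
            "0,0": {"H": 0.45, "HO": 0.55},
        }
    )
    duration_distributions: dict[str, DurationSpec] = field(
        default_factory=lambda: {
            "H": DurationSpec(14.0, 2.0, 8.0, 24.0),
            "W": DurationSpec(8.0, 1.0, 1.0, 14.0),
            "S": DurationSpec(6.0, 1.0, 1.0, 12.0),
            "O": DurationSpec(2.0, 1.0, 0.25, 8.0),
        }
    )
    # Mode utilities: intercept + per_km * distance + car_coeff * has_car.
    mode_utility: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Car": {"const": -0.8, "per_km": -0.08, "car_coeff": 2.5},
            "CarPassenger": {"const": -1.8, "per_km": -0.08, "car_coeff": 0.5},
            "PublicTransport": {"const": -1.0, "per_km": -0.12, "car_coeff": 0.0},
            "Bike": {"const": -0.3, "per_km": -0.50, "car_coeff": 0.0},
            "Walking": {"const": 0.0, "per_km": -1.20, "car_coeff": 0.0},
        }
    )
    # Deterrence rate beta (1/km) per "purpose,mode" key.
    gravity_beta: dict[str, float] = field(
        default_factory=lambda: {
            f"{p},{m}": b
            for p, base in (("W", 0.10), ("S", 0.20), ("O", 0.15))
            for m, mult in (
                ("Car", 1.0),
                ("CarPassenger", 1.1),
                ("PublicTransport", 1.3),
                ("Bike", 2.5),
                ("Walking", 4.0),
            )
            for b in [base * mult]
        }
    )
    # Travel speed per mode (km/h), used to turn distances into diary gaps.
    mode_speed_kmh: dict[str, float] = field(
        default_factory=lambda: {
            "Car": 40.0,
            "CarPassenger": 40.0,
            "PublicTransport": 25.0,
            "Bike": 15.0,
            "Walking": 5.0,
        }
    )
    # Age profiles for employment / studenthood probabilities.
    employment_prob_by_age: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(17, 19, 0.30), (20, 24, 0.60), (25, 64, 0.78), (65, 74, 0.12), (75, 120, 0.02)]
    )
    studenthood_prob_by_age: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(6, 18, 0.95), (19, 24, 0.45), (25, 34, 0.08), (35, 120, 0.01)]
    )
    # P(cars-in-household category | employed) for adults, categories 0,1,2,3+.
    car_probs_employed: list[float] = field(default_factory=lambda: [0.30, 0.48, 0.18, 0.04])
    car_probs_not_employed: list[float] = field(default_factory=lambda: [0.60, 0.32, 0.07, 0.01])
    # P(income class | employed) over No/Low/Lower-middle/Upper-middle/High.
    income_probs_employed: list[float] = field(default_factory=lambda: [0.02, 0.10, 0.28, 0.35, 0.25])
    income_probs_not_employed: list[float] = field(default_factory=lambda: [0.55, 0.30, 0.10, 0.03, 0.02])
    # Commute / trip crow-fly distance distribution (lognormal, km).
    trip_distance_logmean: float = 1.1
    trip_distance_logsd: float = 0.8

    def validate(self) -> None:
        for key, dist in self.participation_probs.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"participation_probs[{key!r}] sums to {total}, expected 1"
                )
            for subset in dist:
                if "H" not in subset:
                    raise ConfigurationError(
                        f"participation_probs[{key!r}] contains a set without H: {subset!r}"
                    )
        for key, beta in self.gravity_beta.items():
            if beta <= 0:
                raise ConfigurationError(f"gravity_beta[{key!r}] must be > 0, got {beta}")
        for probs_name in ("car_probs_employed", "car_probs_not_employed",
                           "income_probs_employed", "income_probs_not_employed"):
            probs = getattr(self, probs_name)
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{probs_name} must sum to 1")


@dataclass
class WorldConfig:
    """Geometry and scale of the generated toy region.

    Zones are rectangles made of whole grid cells, tiled in rows (one row
    of zones per municipality), so zone x grid intersections are exact.
    """

    n_municipalities: int = 2
    zones_per_municipality: int = 5
    persons_per_zone_range: tuple[int, int] = (700, 2700)
    grid_cell_size: float = 1000.0
    cells_per_zone: int = 2
    building_density: dict[str, int] = field(
        default_factory=lambda: {
            "detached_house": 40,
            "apartment": 15,
            "workplace": 10,
            "school": 2,
            "other": 8,
        }
    )
    survey_size: int = 2000
    od_total_per_origin: float = 1000.0
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_municipalities < 1:
            raise ConfigurationError("n_municipalities must be >= 1")
        if self.zones_per_municipality < 1:
            raise ConfigurationError("zones_per_municipality must be >= 1")
        lo, hi = self.persons_per_zone_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                f"persons_per_zone_range must satisfy 0 < min <= max, got {self.persons_per_zone_range}"
            )
        if self.grid_cell_size <= 0:
            raise ConfigurationError("grid_cell_size must be > 0")
        if self.cells_per_zone < 1:
            raise ConfigurationError("cells_per_zone must be >= 1")
        if self.survey_size < 1:
            raise ConfigurationError("survey_size must be >= 1")
        for usage in ("detached_house", "apartment"):
            if self.building_density.get(usage, 0) < 1:
                raise ConfigurationError(
                    f"building_density[{usage!r}] must be >= 1 (households need homes)"
                )
        self.behaviour.validate()


@dataclass
class PopsynthConfig:
    ipf_tol: float = 1e-6
    ipf_max_iter: int = 1000
    # Couple matching: partner-rank proxy = age + Normal(mean, sd) offset.
    age_proxy_mean: float = -2.0
    age_proxy_sd: float = 4.0
    # Child-to-household eligibility window on (adult age - child age).
    child_min_gap: int = 18
    child_max_gap: int = 50
    other_hh_size_range: tuple[int, int] = (2, 6)


@dataclass
class AttributesConfig:
    # Household car count aggregation over member counts: "max" or "sum".
    household_cars: str = "max"
    ipf_tol: float = 1e-8
    ipf_max_iter: int = 5000


@dataclass
class ActivitiesConfig:
    max_tries: int = 100
    # Daily travel-time class edges in hours: (0,0.5], (0.5,1], (1,2], (2,4].
    tt_bin_edges: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)


@dataclass
class LocationConfig:
    # P(detached house | household size) = logistic(intercept + slope*size).
    detached_intercept: float = -3.0
    detached_slope: float = 1.2
    # Probability that a short trip's mode is replaced by Walking.
    walk_substitution_prob: float = 0.0
    # "euclidean" on planar coordinates, or "haversine" for lon/lat inputs.
    distance_metric: str = "euclidean"


@dataclass
class Config:
    """Resolved configuration for a full pipeline run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    popsynth: PopsynthConfig = field(default_factory=PopsynthConfig)
    attributes: AttributesConfig = field(default_factory=AttributesConfig)
    activities: ActivitiesConfig = field(default_factory=ActivitiesConfig)
    location: LocationConfig = field(default_factory=LocationConfig)

    def validate(self) -> None:
        self.world.validate()
        if self.attributes.household_cars not in ("max", "sum"):
            raise ConfigurationError("attributes.household_cars must be 'max' or 'sum'")
        edges = self.activities.tt_bin_edges
        if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
            raise ConfigurationError("activities.tt_bin_edges must be strictly increasing")


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise ConfigurationError(f"unknown configuration key: {path}{key}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def _from_dict(data: dict) -> Config:
    defaults = asdict(Config())
    merged = _merge(defaults, data)
    behaviour = merged["world"].pop("behaviour")
    durations = {
        k: DurationSpec(**v) if isinstance(v, dict) else v
        for k, v in behaviour.pop("duration_distributions").items()
    }
    emp = [tuple(t) for t in behaviour.pop("employment_prob_by_age")]
    stu = [tuple(t) for t in behaviour.pop("studenthood_prob_by_age")]
    params = BehaviourParams(
        duration_distributions=durations,
        employment_prob_by_age=emp,
        studenthood_prob_by_age=stu,
        **behaviour,
    )
    merged["world"]["persons_per_zone_range"] = tuple(merged["world"]["persons_per_zone_range"])
    world = WorldConfig(behaviour=params, **merged["world"])
    pops = merged["popsynth"]
    pops["other_hh_size_range"] = tuple(pops["other_hh_size_range"])
    acts = merged["activities"]
    acts["tt_bin_edges"] = tuple(acts["tt_bin_edges"])
    cfg = Config(
        world=world,
        popsynth=PopsynthConfig(**pops),
        attributes=AttributesConfig(**merged["attributes"]),
        activities=ActivitiesConfig(**acts),
        location=LocationConfig(**merged["location"]),
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML configuration, merged over defaults; None gives defaults."""
    if path is None:
        cfg = Config()
        cfg.validate()
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration file {path} must contain a mapping")
    return _from_dict(data)


def dump_config(config: Config, path: str | Path) -> None:
    """Write the resolved configuration as YAML (provenance copy)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
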