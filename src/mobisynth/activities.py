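"""Stage 2: activity generation.

For each agent: an activity participation set (always containing home), a
joint draw of per-type duration classes and a daily travel-time range
class, concrete durations satisfying the daily time budget

    24 h - tt_upper  <=  t_H + t_W + t_S + t_O  <  24 h - tt_lower,

a donor-matched activity sequence (nearest neighbour in duration space
among survey respondents with the same participation set), and a timed
schedule on the day anchored at 3 AM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import ActivitiesConfig
from .errors import DataError, FeasibilityError
from . import vocab
from .vocab import PURPOSES

DURATION_CLASSES = ["low", "moderate", "high"]

# Fallback sequences when no survey donor shares the participation set.
CANONICAL_FALLBACK = {
    "H": ["H"],
    "HW": ["H", "W", "H"],
    "HS": ["H", "S", "H"],
    "HO": ["H", "O", "H"],
    "HOW": ["H", "W", "O", "H"],
    "HOS": ["H", "S", "O", "H"],
    "HSW": ["H", "W", "S", "H"],
    "HOSW": ["H", "W", "S", "O", "H"],
}


@dataclass
class Schedule:
    """Ordered timed episodes on the 3 AM-anchored day (relative hours)."""

    pid: int
    episodes: list[dict]            # purpose, start_rel, end_rel
    sequence: list[str]
    durations: dict[str, float]     # per-type daily totals
    travel_total: float
    tt_class: tuple[float, float]
    fallback_durations: bool = False
    fallback_sequence: bool = False

    @property
    def n_trips(self) -> int:
        return max(len(self.episodes) - 1, 0)

    def gaps(self) -> list[float]:
        return [self.episodes[i + 1]["start_rel"] - self.episodes[i]["end_rel"]
                for i in range(len(self.episodes) - 1)]


def condensed_sequence(purposes: list[str]) -> list[str]:
    """Collapse consecutive duplicate purposes."""
    out = []
    for p in purposes:
        if not out or out[-1] != p:
            out.append(p)
    return out


def diary_features(survey_persons: pd.DataFrame,
                   survey_diary: pd.DataFrame) -> pd.DataFrame:
    """Per-respondent diary summary used throughout activity generation.

    Columns: participation (sorted purpose string), per-type duration
    totals t_H..t_O, travel_total, sequence (list of purposes), and the
    post-3AM length of the anchor episode.  Episode durations are measured
    on the 3 AM-anchored timeline (first and last rows are the two halves
    of the single anchor episode).
    """
    rows = []
    for rid, g in survey_diary.groupby("respondent_id"):
        g = g.sort_values("episode_id")
        purposes = list(g["purpose"])
        start = (g["start_h"].to_numpy(float) - 3.0) % 24.0
        end = (g["end_h"].to_numpy(float) - 3.0) % 24.0
        end[-1] = 24.0 if end[-1] == 0.0 else end[-1]
        durs = dict.fromkeys(PURPOSES, 0.0)
        for p, s, e in zip(purposes, start, end):
            durs[p] += e - s
        total = sum(durs.values())
        rows.append(
            {"respondent_id": rid,
             "participation": "".join(sorted(set(purposes))),
             "t_H": durs["H"], "t_W": durs["W"], "t_S": durs["S"], "t_O": durs["O"],
             "travel_total": 24.0 - total,
             "sequence": purposes,
             "anchor_end_rel": float(end[0])}
        )
    feats = pd.DataFrame(rows)
    return feats.merge(survey_persons, on="respondent_id")


class ParticipationModel:
    """P(participation set | employment, studenthood), from the survey.

    Empirical conditional distribution over the eight home-containing
    subsets; unseen (employment, studenthood) combinations back off to the
    pooled distribution.  Every subset contains H by construction.
    """

    def __init__(self, features: pd.DataFrame):
        self.by_group: dict[tuple[int, int], pd.Series] = {}
        for (emp, stud), g in features.groupby(["employment", "studenthood"]):
            self.by_group[(int(emp), int(stud))] = (
                g["participation"].value_counts(normalize=True).sort_index()
            )
        self.pooled = features["participation"].value_counts(normalize=True).sort_index()

    def sample(self, employment: int, studenthood: int,
               rng: np.random.Generator) -> str:
        dist = self.by_group.get((int(employment), int(studenthood)), self.pooled)
        k = rng.choice(len(dist), p=dist.to_numpy())
        return str(dist.index[k])


def assign_participation(persons: pd.DataFrame, model: ParticipationModel,
                         rng: np.random.Generator) -> pd.Series:
    """One participation set per person (sorted purpose string, H always in)."""
    out = [model.sample(emp, stud, rng)
           for emp, stud in zip(persons["employment"], persons["studenthood"])]
    return pd.Series(out, index=persons.index, name="participation")


class DurationClassModel:
    """Joint sampler of per-type duration classes and travel-time class.

    Duration-class boundaries are the empirical tertiles of the survey's
    per-type durations.  Class combinations and the travel-time range
    class are drawn *jointly* from the empirical distribution conditioned
    on (participation set, employment, studenthood), backing off to the
    participation set alone, so cross-type correlations survive.
    """

    def __init__(self, features: pd.DataFrame, tt_bin_edges: tuple[float, ...]):
        self.tt_edges = tuple(tt_bin_edges)
        self.tertiles: dict[str, tuple[float, float]] = {}
        for p in PURPOSES:
            vals = features.loc[features["participation"].str.contains(p), f"t_{p}"]
            if len(vals) >= 3:
                q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
            else:
                q1, q2 = 0.0, np.inf
            self.tertiles[p] = (float(q1), float(q2))

        def label(row) -> tuple:
            classes = tuple(
                self.classify(p, row[f"t_{p}"]) for p in row["participation"]
            )
            return classes + (self.tt_class_of(row["travel_total"]),)

        labels = features.apply(label, axis=1)
        self.joint: dict[tuple, pd.Series] = {}
        key_cols = list(zip(features["participation"], features["employment"],
                            features["studenthood"]))
        frame = pd.DataFrame({"key": key_cols, "participation": features["participation"],
                              "label": labels})
        for key, g in frame.groupby("key"):
            self.joint[key] = g["label"].value_counts(normalize=True).sort_index()
        self.by_participation: dict[str, pd.Series] = {}
        for part, g in frame.groupby("participation"):
            self.by_participation[part] = g["label"].value_counts(normalize=True).sort_index()

    def classify(self, purpose: str, duration: float) -> str:
        q1, q2 = self.tertiles[purpose]
        if duration <= q1:
            return "low"
        if duration <= q2:
            return "moderate"
        return "high"

    def tt_class_of(self, travel_total: float) -> tuple[float, float]:
        edges = self.tt_edges
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo < travel_total <= hi:
                return (lo, hi)
        if travel_total <= edges[0]:
            return (edges[0], edges[1])
        return (edges[-2], edges[-1])

    def sample(self, participation: str, employment: int, studenthood: int,
               rng: np.random.Generator) -> tuple[dict[str, str], tuple[float, float]]:
        dist = self.joint.get((participation, int(employment), int(studenthood)))
        if dist is None:
            dist = self.by_participation.get(participation)
        if dist is None:
            # no donor at all: moderate everything, shortest travel class
            classes = {p: "moderate" for p in participation}
            return classes, (self.tt_edges[0], self.tt_edges[1])
        k = rng.choice(len(dist), p=dist.to_numpy())
        label = dist.index[k]
        classes = dict(zip(participation, label[:-1]))
        return classes, label[-1]


class HourlyDurationModel:
    """Class-conditional hourly duration histograms per activity type.

    Empirical histograms at 1 h resolution from the survey, per (type,
    duration class); a sampled duration is the bin origin plus uniform
    jitter within the hour.
    """

    def __init__(self, features: pd.DataFrame, class_model: DurationClassModel):
        self.bins: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for p in PURPOSES:
            vals = features.loc[features["participation"].str.contains(p), f"t_{p}"]
            for cls in DURATION_CLASSES:
                sub = np.array([v for v in vals if class_model.classify(p, v) == cls])
                if len(sub) == 0:
                    sub = vals.to_numpy() if len(vals) else np.array([1.0])
                hours = np.floor(sub).astype(int)
                uniq, counts = np.unique(hours, return_counts=True)
                self.bins[(p, cls)] = (uniq.astype(float), counts / counts.sum())

    def sample(self, purpose: str, cls: str, rng: np.random.Generator) -> float:
        origins, probs = self.bins[(purpose, cls)]
        k = rng.choice(len(origins), p=probs)
        return float(origins[k]) + float(rng.random())


def duration_band(tt_class: tuple[float, float]) -> tuple[float, float]:
    """Feasible [lower, upper) band for the daily activity-duration sum."""
    lo, hi = tt_class
    return 24.0 - hi, 24.0 - lo


def durations_satisfy(durations: dict[str, float], tt_class: tuple[float, float]) -> bool:
    """Check the daily time-budget constraint (upper bound strict)."""
    total = sum(durations.values())
    band_lo, band_hi = duration_band(tt_class)
    return band_lo <= total < band_hi


def sample_durations(participation: str, classes: dict[str, str],
                     tt_class: tuple[float, float], hourly: HourlyDurationModel,
                     rng: np.random.Generator,
                     max_tries: int = 100) -> tuple[dict[str, float], bool]:
    """Draw per-type durations until they satisfy the daily time budget.

    After ``max_tries`` rejections the last draw is rescaled onto the
    midpoint of the feasible band (flagged via the returned bool).
    Types outside the participation set get duration 0 exactly.
    """
    if participation == "H":
        # stay-at-home day: the single home episode fills the whole day
        return {"H": 24.0}, False
    draw: dict[str, float] = {}
    for _ in range(max_tries):
        draw = {p: hourly.sample(p, classes[p], rng) for p in participation}
        if durations_satisfy(draw, tt_class):
            return draw, False
    band_lo, band_hi = duration_band(tt_class)
    mid = (band_lo + band_hi) / 2
    total = sum(draw.values())
    if total <= 0:
        raise FeasibilityError(
            f"cannot rescale zero-duration draw for participation {participation!r}"
        )
    return {p: d * mid / total for p, d in draw.items()}, True


def _relax_orders(attrs: list[str]) -> list[list[str]]:
    """Attribute-agreement filters, strongest first, dropping one at a time."""
    orders = [attrs]
    current = list(attrs)
    while current:
        current = current[:-1]
        orders.append(list(current))
    return orders


MATCH_ATTRS = ["gender", "age_band", "employment", "studenthood"]


def match_sequences(agents: pd.DataFrame, durations: pd.DataFrame,
                    donor_features: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Donor-matched activity sequences for a batch of agents.

    Candidates are survey respondents with the identical participation
    set, filtered by agreement on gender, age band, employment and
    studenthood; filters are relaxed from the last attribute until the
    candidate set is non-empty.  The winner minimises the Euclidean
    distance between activity-duration tuples (t_H, t_W, t_S, t_O), ties
    to the smallest respondent id.  Agents whose participation set has no
    donor at all fall back to a canonical sequence (flagged).

    Returns (sequence series, fallback flag series) indexed like agents.
    """
    donors = donor_features.copy()
    donors["age_band"] = donors["age"].map(vocab.age_to_band)
    tuple_cols = ["t_H", "t_W", "t_S", "t_O"]

    agents = agents.copy()
    agents["age_band"] = agents["age"].map(vocab.age_to_band)
    out_seq = pd.Series([None] * len(agents), index=agents.index, dtype=object)
    out_fb = pd.Series(False, index=agents.index)

    donor_by_part = {p: g for p, g in donors.groupby("participation")}
    group_cols = ["participation"] + MATCH_ATTRS
    for key, idx in agents.groupby(group_cols).groups.items():
        part = key[0]
        pool = donor_by_part.get(part)
        if pool is None:
            seq = CANONICAL_FALLBACK.get(part)
            if seq is None:
                raise DataError(f"no donor and no canonical sequence for {part!r}")
            for i in idx:
                out_seq.at[i] = list(seq)
                out_fb.at[i] = True
            continue
        candidates = pool
        for attrs in _relax_orders(MATCH_ATTRS):
            m = np.ones(len(pool), dtype=bool)
            for a, val in zip(MATCH_ATTRS, key[1:]):
                if a in attrs:
                    m &= (pool[a] == val).to_numpy()
            if m.any():
                candidates = pool[m]
                break
        cand_xy = candidates[tuple_cols].to_numpy(float)
        cand_rid = candidates["respondent_id"].to_numpy()
        # stable winner under ties: order candidates by respondent id
        order = np.argsort(cand_rid, kind="stable")
        cand_xy, cand_rid = cand_xy[order], cand_rid[order]
        cand_seq = [candidates["sequence"].iloc[i] for i in order]
        agent_xy = durations.loc[idx, tuple_cols].to_numpy(float)
        dist = cdist(agent_xy, cand_xy)
        winners = np.argmin(dist, axis=1)  # argmin takes the first == lowest rid
        for i, w in zip(idx, winners):
            out_seq.at[i] = list(cand_seq[w])
    return out_seq, out_fb


def anchor_and_build_schedule(pid: int, sequence: list[str],
                              durations: dict[str, float],
                              tt_class: tuple[float, float],
                              anchor_end_rel: float | None = None) -> Schedule:
    """Lay the sequence onto the 3 AM-anchored day.

    The anchor episode (first/last sequence entry) spans 3 AM; its portion
    after 3 AM is ``anchor_end_rel`` clamped into the feasible range, or
    half its instance duration when no anchor model value is supplied.
    All other instances of a type share the type's total duration equally,
    and the residual travel time (24 h minus total activity time) is split
    equally over the gaps between consecutive episodes.
    """
    seq = condensed_sequence(sequence)
    if len(seq) > 1 and seq[0] != seq[-1]:
        raise DataError(f"sequence {seq} must start and end with the anchor type")
    active = {p for p in seq}
    if set(durations) - {"H", "W", "S", "O"}:
        raise DataError("unknown purpose in durations")
    total = sum(durations.get(p, 0.0) for p in active)
    travel_total = 24.0 - total
    if len(seq) == 1:
        episodes = [{"purpose": seq[0], "start_rel": 0.0, "end_rel": 24.0}]
        return Schedule(pid, episodes, seq, dict(durations), 0.0, tt_class)
    if travel_total <= 0:
        raise FeasibilityError(
            f"activity durations ({total:.2f} h) leave no time to travel"
        )
    inner = seq[1:-1]
    n_instances = {p: (1 if p == seq[0] else 0) + inner.count(p) for p in active}
    per_instance = {p: durations[p] / n_instances[p] for p in active}
    d_anchor = per_instance[seq[0]]
    if anchor_end_rel is None:
        f = d_anchor / 2.0
    else:
        f = float(np.clip(anchor_end_rel, 0.05 * d_anchor, 0.95 * d_anchor))
    gap = travel_total / (len(seq) - 1)
    episodes = [{"purpose": seq[0], "start_rel": 0.0, "end_rel": f}]
    t = f
    for p in inner:
        t += gap
        episodes.append({"purpose": p, "start_rel": t, "end_rel": t + per_instance[p]})
        t += per_instance[p]
    t += gap
    if abs((t + (d_anchor - f)) - 24.0) > 1e-6:
        raise FeasibilityError("schedule does not tile 24 h")
    episodes.append({"purpose": seq[0], "start_rel": t, "end_rel": 24.0})
    return Schedule(pid, episodes, seq, dict(durations), travel_total, tt_class)


class AnchorModel:
    """Empirical distribution of the anchor episode's post-3AM length,
    conditioned on the anchor activity type."""

    def __init__(self, features: pd.DataFrame):
        self.by_type: dict[str, np.ndarray] = {}
        anchor_type = features["sequence"].map(lambda s: s[0])
        for p, g in features.groupby(anchor_type):
            self.by_type[str(p)] = g["anchor_end_rel"].to_numpy(float)

    def sample(self, purpose: str, rng: np.random.Generator) -> float | None:
        vals = self.by_type.get(purpose)
        if vals is None or len(vals) == 0:
            return None
        return float(vals[rng.integers(len(vals))])


@dataclass
class ActivityStageResult:
    schedules: list[Schedule]
    durations: pd.DataFrame       # per-agent duration tuples and flags
    participation: pd.Series


def generate_activity_schedules(persons: pd.DataFrame, survey_persons: pd.DataFrame,
                                survey_diary: pd.DataFrame, config: ActivitiesConfig,
                                seed: int) -> ActivityStageResult:
    """Run the full activity-generation stage for all agents."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    feats = diary_features(survey_persons, survey_diary)
    part_model = ParticipationModel(feats)
    class_model = DurationClassModel(feats, config.tt_bin_edges)
    hourly = HourlyDurationModel(feats, class_model)
    anchor_model = AnchorModel(feats)

    participation = assign_participation(persons, part_model, rng)

    dur_rows = []
    tt_classes: list[tuple[float, float]] = []
    for i in persons.index:
        part = participation.at[i]
        classes, tt_class = class_model.sample(
            part, persons.at[i, "employment"], persons.at[i, "studenthood"], rng)
        draw, flagged = sample_durations(part, classes, tt_class, hourly, rng,
                                         max_tries=config.max_tries)
        tt_classes.append(tt_class)
        dur_rows.append({"PId": persons.at[i, "PId"],
                         "t_H": draw.get("H", 0.0), "t_W": draw.get("W", 0.0),
                         "t_S": draw.get("S", 0.0), "t_O": draw.get("O", 0.0),
                         "tt_lower": tt_class[0], "tt_upper": tt_class[1],
                         "rescaled": flagged})
    durations = pd.DataFrame(dur_rows, index=persons.index)

    agents = persons.assign(participation=participation)
    sequences, seq_fallback = match_sequences(agents, durations, feats)

    schedules = []
    for pos, i in enumerate(persons.index):
        seq = sequences.at[i]
        dur = {p: durations.at[i, f"t_{p}"] for p in "HWSO"
               if durations.at[i, f"t_{p}"] > 0 or p in participation.at[i]}
        anchor = anchor_model.sample(seq[0], rng) if len(seq) > 1 else None
        sched = anchor_and_build_schedule(int(persons.at[i, "PId"]), seq, dur,
                                          tt_classes[pos], anchor)
        sched.fallback_durations = bool(durations.at[i, "rescaled"])
        sched.fallback_sequence = bool(seq_fallback.at[i])
        schedules.append(sched)
    return ActivityStageResult(schedules=schedules, durations=durations,
                               participation=participation)
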