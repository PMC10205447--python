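"""Evaluation metrics and bit-exact table serialization.

Covers the three published table schemas (person, household,
activity-travel), the evaluation metrics used to assess a synthetic
population — per-zone marginal percentage differences, Jensen-Shannon
distance between duration distributions, per-mode trip-distance
histograms — and their CSV dialects (UTF-8, '.' decimals, clock times and
coordinates with one decimal).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .errors import DataError, ValidationError
from . import vocab


def js_distance(p, q) -> float:
    """Jensen-Shannon distance between two probability vectors.

    Square root of the Jensen-Shannon divergence with base-2 logarithms:
    symmetric, 0 iff p = q, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise DataError("js_distance needs two equal-length vectors")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise DataError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise DataError(f"{name} sums to {v.sum():.12f}, expected 1")
    d = float(jensenshannon(p, q, base=2))
    return 0.0 if np.isnan(d) else d


def histogram_distribution(values, bins) -> np.ndarray:
    """Normalised histogram over fixed bin edges (a probability vector)."""
    counts, _ = np.histogram(np.asarray(values, float), bins=bins)
    total = counts.sum()
    if total == 0:
        raise DataError("no values fall inside the histogram bins")
    return counts / total


def marginal_diff_report(persons: pd.DataFrame,
                         zone_margins: pd.DataFrame) -> pd.DataFrame:
    """Per-zone percentage differences of synthetic vs target marginals.

    One row per (zone, attribute, category):
    (synthetic - target) / target x 100, for gender and age group.  Zones
    present in the targets but absent from the persons are reported with
    status 'missing' rather than raising.
    """
    rows = []
    present = set(persons["zone_id"].unique()) if len(persons) else set()
    for zone_id, zg in zone_margins.groupby("zone_id"):
        if zone_id not in present:
            for attr in ("gender", "age_group"):
                rows.append({"zone_id": zone_id, "attribute": attr, "category": "*",
                             "target": int(zg["count"].sum()), "synthetic": 0,
                             "pct_diff": np.nan, "status": "missing"})
            continue
        zp = persons[persons["zone_id"] == zone_id]
        for attr in ("gender", "age_group"):
            target = zg.groupby(attr)["count"].sum()
            synth = zp.groupby(attr).size()
            for cat, tgt in target.items():
                s = int(synth.get(cat, 0))
                pct = np.nan if tgt == 0 else (s - tgt) / tgt * 100.0
                rows.append({"zone_id": zone_id, "attribute": attr, "category": cat,
                             "target": int(tgt), "synthetic": s,
                             "pct_diff": pct, "status": "ok"})
    return pd.DataFrame(rows)


def marginal_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Share of zones with every category within +/-0.5% and +/-1% bands."""
    rows = []
    ok = report[report["status"] == "ok"]
    for attr, g in ok.groupby("attribute"):
        per_zone = g.groupby("zone_id")["pct_diff"].agg(lambda s: s.abs().max())
        rows.append({"attribute": attr,
                     "share_within_0.5pct": float((per_zone <= 0.5).mean()),
                     "share_within_1pct": float((per_zone <= 1.0).mean()),
                     "n_zones": int(len(per_zone))})
    return pd.DataFrame(rows)


def trip_distance_distributions(activity_table: pd.DataFrame,
                                bins=None) -> pd.DataFrame:
    """Per-mode histogram of consecutive-activity straight-line distances (km)."""
    if bins is None:
        bins = np.arange(0.0, 21.0, 1.0)
    rows = []
    for pid, g in activity_table.groupby("PId"):
        g = g.sort_values("activity_id")
        xs, ys = g["x"].to_numpy(float), g["y"].to_numpy(float)
        modes = g["mode"].to_numpy()
        for i in range(1, len(g)):
            if modes[i] == "":
                continue
            dist = float(np.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1])) / 1000.0
            rows.append({"mode": modes[i], "distance_km": dist})
    trips = pd.DataFrame(rows)
    out = []
    for mode, g in trips.groupby("mode"):
        counts, edges = np.histogram(g["distance_km"], bins=bins)
        total = counts.sum()
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            out.append({"mode": mode, "bin_low_km": lo, "bin_high_km": hi,
                        "count": int(c),
                        "share": float(c / total) if total else 0.0})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# published table schemas

PERSON_COLUMNS = ["PId", "HId", "Gender", "Age", "Marital status",
                  "Employment status", "Studenthood status", "Income class",
                  "Number of cars", "DeSO", "Municipality"]
PERSON_SNAKE = ["pid", "hid", "gender", "age", "marital_status",
                "employment_status", "studenthood_status", "income_class",
                "number_of_cars", "deso", "municipality"]

HOUSEHOLD_COLUMNS = ["HId", "Type", "Size", "Number of children", "Number of cars"]
HOUSEHOLD_SNAKE = ["hid", "type", "size", "number_of_children", "number_of_cars"]

ACTIVITY_COLUMNS = ["PId", "Activity ID", "Activity Purpose", "Activity Start Time",
                    "Activity End Time", "Travel Mode", "Building ID",
                    "Building Type", "Point X", "Point Y", "DeSO"]
ACTIVITY_SNAKE = ["pid", "activity_id", "activity_purpose", "activity_start_time",
                  "activity_end_time", "travel_mode", "building_id",
                  "building_type", "point_x", "point_y", "deso"]

_MARITAL_ALIASES = {"age<18": "age<18", "Age < 18": "age<18",
                    "couple": "couple", "single": "single"}
_INCOME_ALIASES = {c: c for c in vocab.INCOME_CLASSES}
_INCOME_ALIASES.update({str(i): c for i, c in enumerate(vocab.INCOME_CLASSES)})
PURPOSE_VOCAB = list(vocab.PURPOSE_NAMES.values())
MODE_VOCAB = vocab.MODES
BUILDING_TYPE_VOCAB = ["Detached house", "Apartment", "Other"]


def _fmt1(x: float) -> str:
    return f"{float(x):.1f}"


def write_person_table(persons: pd.DataFrame, path: str | Path,
                       snake_case: bool = False) -> None:
    """Write the person table with the published header.

    Expects internal columns PId, HId, gender, age, marital_status,
    employment, studenthood, income_class, n_cars, zone_id, municipality_id.
    """
    df = pd.DataFrame({
        "PId": persons["PId"].astype(int),
        "HId": persons["HId"].astype(int),
        "Gender": persons["gender"],
        "Age": persons["age"].astype(int),
        "Marital status": persons["marital_status"],
        "Employment status": persons["employment"].astype(int),
        "Studenthood status": persons["studenthood"].astype(int),
        "Income class": persons["income_class"],
        "Number of cars": persons["n_cars"].astype(int),
        "DeSO": persons["zone_id"],
        "Municipality": persons["municipality_id"],
    })
    if snake_case:
        df.columns = PERSON_SNAKE
    df.to_csv(path, index=False)


def read_person_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a person table; returns internal column names."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == PERSON_COLUMNS or cols == PERSON_SNAKE:
        df.columns = PERSON_COLUMNS
    else:
        raise ValidationError(f"person table has unexpected header: {cols}")
    out = pd.DataFrame({
        "PId": df["PId"].astype(int), "HId": df["HId"].astype(int),
        "gender": df["Gender"].astype(str), "age": df["Age"].astype(int),
        "marital_status": df["Marital status"].astype(str),
        "employment": df["Employment status"].astype(int),
        "studenthood": df["Studenthood status"].astype(int),
        "income_class": df["Income class"].astype(str),
        "n_cars": df["Number of cars"].astype(int),
        "zone_id": df["DeSO"].astype(str),
        "municipality_id": df["Municipality"].astype(str),
    })
    for i, g in enumerate(out["gender"]):
        if g not in vocab.GENDERS:
            raise ValidationError(f"unknown Gender {g!r}", row=i + 2)
    out["marital_status"] = _map_vocab(out["marital_status"], _MARITAL_ALIASES,
                                       "Marital status")
    out["income_class"] = _map_vocab(out["income_class"], _INCOME_ALIASES,
                                     "Income class")
    return out


def _map_vocab(series: pd.Series, aliases: dict, name: str) -> pd.Series:
    out = series.map(aliases)
    if out.isna().any():
        i = int(out.index[out.isna()][0])
        raise ValidationError(f"unknown {name} {series.iloc[i]!r}", row=i + 2)
    return out


def write_household_table(households: pd.DataFrame, path: str | Path,
                          snake_case: bool = False) -> None:
    df = pd.DataFrame({
        "HId": households["HId"].astype(int),
        "Type": households["type"],
        "Size": households["size"].astype(int),
        "Number of children": households["n_children_under6"].astype(int),
        "Number of cars": households["n_cars"].astype(int),
    })
    if snake_case:
        df.columns = HOUSEHOLD_SNAKE
    df.to_csv(path, index=False)


def read_household_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == HOUSEHOLD_COLUMNS or cols == HOUSEHOLD_SNAKE:
        df.columns = HOUSEHOLD_COLUMNS
    else:
        raise ValidationError(f"household table has unexpected header: {cols}")
    out = pd.DataFrame({
        "HId": df["HId"].astype(int), "type": df["Type"].astype(str),
        "size": df["Size"].astype(int),
        "n_children_under6": df["Number of children"].astype(int),
        "n_cars": df["Number of cars"].astype(int),
    })
    for i, t in enumerate(out["type"]):
        if t not in vocab.HOUSEHOLD_TYPES:
            raise ValidationError(f"unknown household Type {t!r}", row=i + 2)
    if (out["size"] < 1).any():
        i = int(out.index[out["size"] < 1][0])
        raise ValidationError("household Size must be >= 1", row=i + 2)
    return out


def write_activity_table(table: pd.DataFrame, path: str | Path,
                         snake_case: bool = False) -> None:
    """Write the activity-travel table: decimal clock hours and coordinates
    with one decimal, empty travel mode on each day's first row."""
    df = pd.DataFrame({
        "PId": table["PId"].astype(int),
        "Activity ID": table["activity_id"].astype(int),
        "Activity Purpose": table["purpose"],
        "Activity Start Time": table["start_h"].map(_fmt1),
        "Activity End Time": table["end_h"].map(_fmt1),
        "Travel Mode": table["mode"],
        "Building ID": table["building_id"].astype(int),
        "Building Type": table["building_type"],
        "Point X": table["x"].map(_fmt1),
        "Point Y": table["y"].map(_fmt1),
        "DeSO": table["zone_id"],
    })
    if snake_case:
        df.columns = ACTIVITY_SNAKE
    df.to_csv(path, index=False)


def read_activity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    cols = list(df.columns)
    if cols == ACTIVITY_COLUMNS or cols == ACTIVITY_SNAKE:
        df.columns = ACTIVITY_COLUMNS
    else:
        raise ValidationError(f"activity table has unexpected header: {cols}")
    out = pd.DataFrame({
        "PId": df["PId"].astype(int),
        "activity_id": df["Activity ID"].astype(int),
        "purpose": df["Activity Purpose"].astype(str),
        "start_h": df["Activity Start Time"].astype(float),
        "end_h": df["Activity End Time"].astype(float),
        "mode": df["Travel Mode"].astype(str),
        "building_id": df["Building ID"].astype(int),
        "building_type": df["Building Type"].astype(str),
        "x": df["Point X"].astype(float),
        "y": df["Point Y"].astype(float),
        "zone_id": df["DeSO"].astype(str),
    })
    for i, p in enumerate(out["purpose"]):
        if p not in PURPOSE_VOCAB:
            raise ValidationError(f"unknown Activity Purpose {p!r}", row=i + 2)
    for i, m in enumerate(out["mode"]):
        if m != "" and m not in MODE_VOCAB:
            raise ValidationError(f"unknown Travel Mode {m!r}", row=i + 2)
    for i, b in enumerate(out["building_type"]):
        if b not in BUILDING_TYPE_VOCAB:
            raise ValidationError(f"unknown Building Type {b!r}", row=i + 2)
    return out
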