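"""Stage 1: population synthesis.

Estimates the zone-level joint distribution of gender x age group x civil
status by iterative proportional fitting (IPF) seeded with the municipal
cross-tabulation, instantiates agents with basic attributes, and groups
them into single / couple / other households.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PopsynthConfig
from .errors import ConvergenceError, DataError, FeasibilityError
from . import vocab
from .vocab import AGE_BAND_LABELS, GENDERS, MARITAL


@dataclass
class IPFResult:
    table: np.ndarray
    n_iter: int
    max_residual: float


def ipf_fit(seed_table: np.ndarray, marginals: list[np.ndarray], tol: float = 1e-6,
            max_iter: int = 1000) -> IPFResult:
    """Iterative proportional fitting of an N-way table to axis marginals.

    Alternately rescales each axis of ``seed_table`` so its marginal matches
    the target vector, preserving the seed's cross-product ratios where the
    seed is positive.  Structural zeros stay zero.

    Parameters
    ----------
    seed_table
        Non-negative array with one axis per marginal.
    marginals
        One non-negative target vector per axis; all must share the same
        grand total (within 1e-6 relative).

    Returns the fitted table with the iteration count and the final maximum
    absolute marginal residual.
    """
    table = np.asarray(seed_table, dtype=float).copy()
    if np.any(table < 0):
        raise DataError("seed table contains negative cells")
    if table.ndim != len(marginals):
        raise DataError(
            f"seed table has {table.ndim} axes but {len(marginals)} marginals given"
        )
    targets = [np.asarray(m, dtype=float) for m in marginals]
    for axis, target in enumerate(targets):
        if len(target) != table.shape[axis]:
            raise DataError(f"marginal for axis {axis} has wrong length")
        if np.any(target < 0):
            raise DataError(f"marginal for axis {axis} contains negative entries")
    totals = [t.sum() for t in targets]
    scale = max(max(totals), 1.0)
    if max(totals) - min(totals) > 1e-6 * scale:
        raise DataError(
            f"marginal grand totals disagree: {totals} (must match within 1e-6)"
        )
    # a slice with zero seed mass cannot absorb positive target mass
    for axis, target in enumerate(targets):
        other = tuple(a for a in range(table.ndim) if a != axis)
        margin = table.sum(axis=other)
        bad = (margin == 0) & (target > 0)
        if np.any(bad):
            raise DataError(
                f"axis {axis} slice(s) {np.nonzero(bad)[0].tolist()} have zero seed "
                "mass but positive target"
            )

    for it in range(1, max_iter + 1):
        for axis, target in enumerate(targets):
            other = tuple(a for a in range(table.ndim) if a != axis)
            margin = table.sum(axis=other)
            factor = np.ones_like(target)
            nz = margin > 0
            factor[nz] = target[nz] / margin[nz]
            shape = [1] * table.ndim
            shape[axis] = len(target)
            table *= factor.reshape(shape)
        residual = 0.0
        for axis, target in enumerate(targets):
            other = tuple(a for a in range(table.ndim) if a != axis)
            residual = max(residual, float(np.abs(table.sum(axis=other) - target).max()))
        if residual < tol:
            return IPFResult(table, it, residual)
    raise ConvergenceError(
        f"IPF did not converge in {max_iter} iterations (residual {residual:.3g})",
        residual=residual,
    )


def integerize(fitted: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Truncate-replicate-sample integerization.

    Floors every cell, then allocates the remaining units (grand total
    rounded minus the floor sum) one per draw, sampling cells without
    replacement with probability proportional to their fractional parts.
    The output total equals ``round(fitted.sum())`` and no cell moves by
    more than one unit from its floored value.
    """
    values = np.asarray(fitted, dtype=float)
    if np.any(values < 0):
        raise DataError("cannot integerize negative cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = values.ravel()
    floors = np.floor(flat + 1e-9).astype(np.int64)
    remainder = int(round(flat.sum())) - int(floors.sum())
    out = floors.copy()
    if remainder > 0:
        frac = flat - np.floor(flat + 1e-9)
        if frac.sum() <= 0:
            frac = np.ones_like(flat)
        p = frac / frac.sum()
        idx = rng.choice(flat.size, size=remainder, replace=False, p=p)
        out[idx] += 1
    return out.reshape(values.shape)


def synthesize_persons(zone_row: pd.Series, zone_margin: pd.DataFrame,
                       crosstab: pd.DataFrame, config: PopsynthConfig,
                       rng: np.random.Generator, start_pid: int = 1) -> pd.DataFrame:
    """Synthesize one zone's agents with basic attributes.

    The municipal gender x age x civil cross-tab seeds an IPF whose row
    targets are the zone's exact gender x age counts and whose column
    targets are the municipal civil-status shares scaled to the zone
    population.  Each (gender, age) row is integerized separately, so the
    zone's gender and age-group marginals are matched exactly.  Integer
    ages are drawn uniformly within the band, restricted to the side of the
    age-18 boundary implied by the civil status.
    """
    zone_id = zone_row["zone_id"]
    muni = zone_row["municipality_id"]
    n_bands = len(AGE_BAND_LABELS)

    margin = np.zeros((2, n_bands))
    for _, r in zone_margin.iterrows():
        margin[GENDERS.index(r["gender"]), AGE_BAND_LABELS.index(r["age_group"])] = r["count"]

    seed = np.zeros((2, n_bands, len(MARITAL)))
    for _, r in crosstab.iterrows():
        seed[GENDERS.index(r["gender"]), AGE_BAND_LABELS.index(r["age_group"]),
             MARITAL.index(r["civil_status"])] = r["count"]

    # guard: any (gender, band) cell with zone mass needs municipal seed mass
    flat_seed = seed.reshape(2 * n_bands, len(MARITAL))
    row_target = margin.reshape(-1)
    empty = (flat_seed.sum(axis=1) == 0) & (row_target > 0)
    if np.any(empty):
        raise DataError(
            f"zone {zone_id}: municipal cross-tab has no mass for "
            f"{int(empty.sum())} populated gender/age cells"
        )
    # single-margin IPF: scale each municipal (gender, age) slice to the
    # zone count; civil status follows the municipal conditional, so only
    # the gender and age-group marginals are constrained exactly.
    row_mass = flat_seed.sum(axis=1, keepdims=True)
    safe = np.where(row_mass > 0, row_mass, 1.0)
    fitted = flat_seed / safe * row_target[:, None]

    counts = np.zeros_like(flat_seed, dtype=np.int64)
    for i in range(flat_seed.shape[0]):
        row = fitted[i]
        total = int(round(row_target[i]))
        if total == 0:
            continue
        if row.sum() <= 0:
            continue
        scaled = row / row.sum() * total
        counts[i] = integerize(scaled, rng)
    counts = counts.reshape(2, n_bands, len(MARITAL))

    records = []
    pid = start_pid
    for gi, gender in enumerate(GENDERS):
        for bi, band in enumerate(AGE_BAND_LABELS):
            lo, hi = vocab.age_band_bounds(band)
            for ci, civil in enumerate(MARITAL):
                k = int(counts[gi, bi, ci])
                if k == 0:
                    continue
                # civil status pins which side of 18 the age falls on
                a_lo, a_hi = (lo, min(hi, 17)) if civil == "age<18" else (max(lo, 18), hi)
                if a_lo > a_hi:
                    a_lo, a_hi = lo, hi  # inconsistent seed cell; fall back to band
                ages = rng.integers(a_lo, a_hi + 1, size=k)
                for age in ages:
                    records.append(
                        {"PId": pid, "HId": -1, "gender": gender, "age": int(age),
                         "marital_status": civil, "age_group": band,
                         "zone_id": zone_id, "municipality_id": muni}
                    )
                    pid += 1
    return pd.DataFrame(records)


def form_households(persons: pd.DataFrame, zone_targets: pd.Series,
                    config: PopsynthConfig, rng: np.random.Generator,
                    start_hid: int = 1) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Group one zone's persons into single / couple / other households.

    Couples: couple-status persons split by gender; one group ordered by
    age, the other by a noisy age proxy (age + Normal offset), matched
    one-to-one in rank order up to the zone's couple target.  Singles fill
    single households up to target.  Children (<18) join the eligible
    household whose qualifying adult is closest in age (the gap must lie in
    the configured window), ties to the lower household id.  Everyone left
    is pooled into 'other' households of the configured size range.

    Returns (households, persons-with-HId, warnings).
    """
    persons = persons.copy().reset_index(drop=True)
    warnings: list[str] = []
    hid = start_hid
    membership: dict[int, list[int]] = {}   # HId -> list of person indices
    htype: dict[int, str] = {}
    assigned = np.zeros(len(persons), dtype=bool)

    def targets_get(key: str) -> int:
        return int(zone_targets.get(key, 0))

    # --- couples ---------------------------------------------------------
    couple_idx = persons.index[persons["marital_status"] == "couple"]
    group1 = persons.loc[couple_idx][persons.loc[couple_idx, "gender"] == GENDERS[0]]
    group2 = persons.loc[couple_idx][persons.loc[couple_idx, "gender"] == GENDERS[1]]
    order1 = group1.sort_values(["age", "PId"]).index.to_numpy()
    proxy = group2["age"].to_numpy(float) + rng.normal(
        config.age_proxy_mean, config.age_proxy_sd, size=len(group2))
    order2 = group2.index.to_numpy()[np.lexsort((group2["PId"].to_numpy(), proxy))]
    target_couple = targets_get("n_households_couple")
    n_pairs = min(len(order1), len(order2), target_couple)
    if target_couple > min(len(order1), len(order2)):
        warnings.append(
            f"couple target {target_couple} capped to {n_pairs} (insufficient partners)"
        )
    for k in range(n_pairs):
        membership[hid] = [int(order1[k]), int(order2[k])]
        htype[hid] = "couple"
        assigned[order1[k]] = assigned[order2[k]] = True
        hid += 1

    # --- singles ---------------------------------------------------------
    single_idx = persons.index[
        (persons["marital_status"] == "single") & (persons["age"] >= 18)
    ].to_numpy()
    single_idx = single_idx[rng.permutation(len(single_idx))]
    target_single = targets_get("n_households_single")
    n_single = min(len(single_idx), target_single)
    if target_single > len(single_idx):
        warnings.append(
            f"single target {target_single} capped to {n_single} (insufficient singles)"
        )
    for k in range(n_single):
        membership[hid] = [int(single_idx[k])]
        htype[hid] = "single"
        assigned[single_idx[k]] = True
        hid += 1

    # --- children --------------------------------------------------------
    child_idx = persons.index[persons["age"] < 18].to_numpy()
    hh_adult_ages = {
        h: [(persons.at[i, "age"]) for i in members]
        for h, members in membership.items()
    }
    for ci in sorted(child_idx, key=lambda i: int(persons.at[i, "PId"])):
        child_age = int(persons.at[ci, "age"])
        best_h, best_gap = None, None
        for h in sorted(membership):
            gaps = [a - child_age for a in hh_adult_ages[h]
                    if config.child_min_gap <= a - child_age <= config.child_max_gap]
            if not gaps:
                continue
            gap = min(gaps)
            if best_gap is None or gap < best_gap:
                best_h, best_gap = h, gap
        if best_h is not None:
            membership[best_h].append(int(ci))
            assigned[ci] = True

    # --- other: pool every unassigned person -----------------------------
    pool = persons.index[~assigned].to_numpy()
    pool = pool[rng.permutation(len(pool))]
    lo, hi = config.other_hh_size_range
    pos = 0
    while pos < len(pool):
        size = int(rng.integers(lo, hi + 1))
        chunk = pool[pos:pos + size]
        membership[hid] = [int(i) for i in chunk]
        htype[hid] = "other"
        hid += 1
        pos += size

    hids = np.full(len(persons), -1, dtype=np.int64)
    hh_rows = []
    for h in sorted(membership):
        members = membership[h]
        for i in members:
            hids[i] = h
        ages = persons.loc[members, "age"]
        hh_rows.append(
            {"HId": h, "type": htype.get(h, "other"), "size": len(members),
             "n_children_under6": int((ages < 6).sum()), "n_cars": 0,
             "zone_id": persons.at[members[0], "zone_id"]}
        )
    if np.any(hids < 0):
        raise FeasibilityError("some persons left without a household")
    persons = persons.assign(HId=hids)
    return pd.DataFrame(hh_rows), persons, warnings


def synthesize_population(world, config: PopsynthConfig,
                          seed: int) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Run person synthesis and household formation for every zone."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    margins = {z: g for z, g in world.zone_margins.groupby("zone_id")}
    crosstabs = {m: g for m, g in world.crosstabs.groupby("municipality_id")}
    all_persons, all_households, warnings = [], [], []
    pid = hid = 1
    for _, zone_row in world.zones.sort_values("zone_id").iterrows():
        zp = synthesize_persons(zone_row, margins[zone_row["zone_id"]],
                                crosstabs[zone_row["municipality_id"]],
                                config, rng, start_pid=pid)
        pid += len(zp)
        hh, zp, warns = form_households(zp, zone_row, config, rng, start_hid=hid)
        hid += len(hh)
        warnings.extend(f"{zone_row['zone_id']}: {w}" for w in warns)
        all_persons.append(zp)
        all_households.append(hh)
    persons = pd.concat(all_persons, ignore_index=True)
    households = pd.concat(all_households, ignore_index=True)
    return persons, households, warnings
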