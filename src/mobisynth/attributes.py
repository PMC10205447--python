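"""Stage 1b: advanced attribute assignment.

Implements the generative probabilistic model: a pluggable per-person
choice-probability model (default: multinomial logistic regression),
biproportional (IPF) adjustment of the person x category probability matrix
to aggregate category targets, and independent categorical sampling.
Applied in sequence to joint employment/studenthood, income class, and car
ownership, each conditioning on the previously assigned attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .config import AttributesConfig
from .errors import DataError, FeasibilityError
from .popsynth import ipf_fit
from .vocab import (EMPLOYMENT_STUDENT_CATEGORIES, INCOME_CLASSES,
                    MIN_EMPLOYMENT_AGE)


@dataclass
class ChoiceModel:
    """Probabilistic classifier over an ordered choice set.

    ``predict`` maps a feature frame to an (n, k) matrix of per-person
    probability vectors (rows sum to 1); deterministic given features.
    """

    choice_set: list[str]
    features: list[str]
    _pipeline: Pipeline

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        probs = self._pipeline.predict_proba(X[self.features])
        # reorder columns to the declared choice set
        order = [list(self._pipeline.classes_).index(c) for c in self.choice_set]
        return probs[:, order]


def train_choice_model(survey: pd.DataFrame, features: list[str], target: str,
                       choice_set: list[str] | None = None) -> ChoiceModel:
    """Fit the default multinomial logistic-regression choice model.

    The contract admits any drop-in probabilistic classifier (e.g. a shallow
    neural network); with an intercept term the logistic model reproduces
    the observed class shares in aggregate on its training data.
    """
    if target not in survey.columns:
        raise DataError(f"survey lacks target column {target!r}")
    y = survey[target].astype(str)
    observed = sorted(y.unique())
    if len(observed) < 2:
        raise DataError(
            f"target {target!r} has a single observed class ({observed[0]!r}); "
            "cannot fit a choice model"
        )
    if choice_set is None:
        choice_set = observed
    elif set(observed) - set(choice_set):
        raise DataError(f"observed classes {observed} outside choice set {choice_set}")
    X = survey[features]
    categorical = [f for f in features if X[f].dtype == object or str(X[f].dtype) == "category"]
    numeric = [f for f in features if f not in categorical]
    pre = ColumnTransformer(
        [("cat", OneHotEncoder(handle_unknown="ignore"), categorical),
         ("num", StandardScaler(), numeric)]
    )
    pipeline = Pipeline(
        [("pre", pre),
         ("clf", LogisticRegression(max_iter=2000, C=1.0))]
    )
    pipeline.fit(X, y)
    present = [c for c in choice_set if c in set(observed)]
    return ChoiceModel(choice_set=present, features=list(features), _pipeline=pipeline)


def fit_probabilities(probabilities: np.ndarray, targets: np.ndarray,
                      categories: list[str] | None = None,
                      tol: float = 1e-8, max_iter: int = 5000) -> np.ndarray:
    """Biproportional (IPF) adjustment of per-person probability vectors.

    Rows are persons (target mass 1 each), columns are categories with the
    desired totals.  Targets are rescaled proportionally so they sum to the
    number of persons; structural zeros in the input stay zero.
    """
    P = np.asarray(probabilities, dtype=float)
    t = np.asarray(targets, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(t):
        raise DataError("probability matrix and targets have incompatible shapes")
    if np.any(t < 0):
        raise DataError("category targets must be non-negative")
    n = P.shape[0]
    if t.sum() <= 0:
        raise DataError("category targets sum to zero")
    t = t / t.sum() * n
    col_mass = P.sum(axis=0)
    bad = (col_mass <= 0) & (t > 1e-12)
    if np.any(bad):
        names = [categories[i] if categories else str(i) for i in np.nonzero(bad)[0]]
        raise FeasibilityError(
            f"categories {names} have positive targets but zero probability mass"
        )
    fit = ipf_fit(P, [np.ones(n), t], tol=tol, max_iter=max_iter)
    return fit.table


def sample_choices(adjusted: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Draw one category index per row by independent categorical sampling."""
    P = np.asarray(adjusted, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = P / P.sum(axis=1, keepdims=True)
    u = rng.random(P.shape[0])
    cdf = np.cumsum(rows, axis=1)
    return (u[:, None] > cdf[:, :-1]).sum(axis=1)


def _car_category_targets(probabilities: np.ndarray, target_cars: float) -> np.ndarray:
    """Category person-counts over {0,1,2,3+} consistent with a car total.

    Tilts the model-predicted category counts c_k by t**k (exponential
    tilt, k = cars with 3+ counted as 3) and solves the monotone 1-D root
    so the expected number of cars matches the zone's registered total.
    """
    c = probabilities.sum(axis=0)
    n = probabilities.shape[0]
    k = np.array([0.0, 1.0, 2.0, 3.0])
    active = c > 0
    max_cars = float((k * n * active)[active].max()) if active.any() else 0.0
    target_cars = float(np.clip(target_cars, 1e-9, n * k[active].max() - 1e-9))

    def mean_cars(log_t: float) -> float:
        w = c * np.exp(k * log_t)
        return float((w * k).sum() / w.sum() * n)

    lo, hi = -30.0, 30.0
    if mean_cars(lo) > target_cars or mean_cars(hi) < target_cars:
        # target outside the tiltable range; pin to the closest extreme
        log_t = lo if mean_cars(lo) > target_cars else hi
    else:
        log_t = brentq(lambda x: mean_cars(x) - target_cars, lo, hi, xtol=1e-10)
    w = c * np.exp(k * log_t)
    return w / w.sum() * n


def _employment_student_targets(probabilities: np.ndarray, n_employees: float,
                                n_students: float, n: int) -> np.ndarray:
    """Four joint-category targets from employee and student totals.

    The 'both' total is unobserved; it is taken from the model's predicted
    mass, clipped to the feasible interval [max(0, E+S-N), min(E, S)].
    """
    E = min(float(n_employees), float(n))
    S = min(float(n_students), float(n))
    both_hat = float(probabilities[:, EMPLOYMENT_STUDENT_CATEGORIES.index("both")].sum())
    B = float(np.clip(both_hat, max(0.0, E + S - n), min(E, S)))
    return np.array([n - E - S + B, E - B, S - B, B])


def _assign_categorical(persons: pd.DataFrame, mask: np.ndarray, model: ChoiceModel,
                        targets: np.ndarray, rng: np.random.Generator,
                        config: AttributesConfig,
                        structural_zero: np.ndarray | None = None) -> np.ndarray:
    """Predict, optionally zero out, IPF-adjust and sample for masked rows."""
    sub = persons.loc[mask]
    P = model.predict(sub)
    if structural_zero is not None:
        P = P * (1.0 - structural_zero)
        row_tot = P.sum(axis=1, keepdims=True)
        if np.any(row_tot <= 0):
            raise FeasibilityError("structural zeros removed all probability mass for a person")
        P = P / row_tot
    adjusted = fit_probabilities(P, targets, categories=model.choice_set,
                                 tol=config.ipf_tol, max_iter=config.ipf_max_iter)
    return sample_choices(adjusted, rng)


def assign_advanced_attributes(persons: pd.DataFrame, households: pd.DataFrame,
                               survey: pd.DataFrame, world,
                               config: AttributesConfig,
                               seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign employment x studenthood, income class and car ownership.

    Each attribute is assigned zone-by-zone (income: municipality-wise)
    with the generative model, conditioning on everything assigned before;
    employment is structurally impossible below age 17.  The household car
    count aggregates member counts (max by default, configurable to sum).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    persons = persons.copy()
    survey = survey.copy()

    hh_size = households.set_index("HId")["size"]
    persons["household_size"] = persons["HId"].map(hh_size).astype(int)
    # survey speaks of civil status; synthetic persons carry marital_status
    persons["civil_status"] = persons["marital_status"]

    # --- joint employment x studenthood ---------------------------------
    survey["emp_stud"] = np.select(
        [(survey["employment"] == 1) & (survey["studenthood"] == 1),
         survey["employment"] == 1, survey["studenthood"] == 1],
        ["both", "employed", "student"], default="neither")
    es_model = train_choice_model(
        survey, ["age", "gender", "civil_status", "household_size"], "emp_stud",
        choice_set=EMPLOYMENT_STUDENT_CATEGORIES)
    cats = es_model.choice_set
    emp_cols = np.array([c in ("employed", "both") for c in cats], dtype=float)

    persons["employment"] = 0
    persons["studenthood"] = 0
    zone_counts = world.zones.set_index("zone_id")
    for zone_id, idx in persons.groupby("zone_id").groups.items():
        mask = persons.index.isin(idx)
        sub = persons.loc[mask]
        zero = np.zeros((len(sub), len(cats)))
        zero[(sub["age"] < MIN_EMPLOYMENT_AGE).to_numpy()[:, None]
             & (emp_cols > 0)[None, :]] = 1.0
        P = es_model.predict(sub)
        P = P * (1 - zero)
        P = P / P.sum(axis=1, keepdims=True)
        targets4 = _employment_student_targets(
            P, zone_counts.at[zone_id, "n_employees"],
            zone_counts.at[zone_id, "n_students"], len(sub))
        # feasibility: employable mass must cover the employee target
        employable = int((sub["age"] >= MIN_EMPLOYMENT_AGE).sum())
        emp_target = targets4[1] + targets4[3]
        if emp_target > employable:
            shift = emp_target - employable
            targets4[1] *= employable / emp_target
            targets4[3] *= employable / emp_target
            targets4[0] += shift * targets4[0] / max(targets4[0] + targets4[2], 1e-9)
            targets4[2] = len(sub) - targets4[0] - targets4[1] - targets4[3]
        adjusted = fit_probabilities(P, targets4, categories=cats,
                                     tol=config.ipf_tol, max_iter=config.ipf_max_iter)
        draw = sample_choices(adjusted, rng)
        chosen = np.array(cats)[draw]
        persons.loc[mask, "employment"] = np.isin(chosen, ["employed", "both"]).astype(int)
        persons.loc[mask, "studenthood"] = np.isin(chosen, ["student", "both"]).astype(int)

    # --- income class (municipal targets) --------------------------------
    inc_model = train_choice_model(
        survey, ["age", "gender", "employment", "studenthood"], "income_class",
        choice_set=INCOME_CLASSES)
    persons["income_class"] = "No"
    income = world.municipal_income.set_index(["municipality_id", "income_class"])["count"]
    for muni, idx in persons.groupby("municipality_id").groups.items():
        mask = persons.index.isin(idx)
        sub = persons.loc[mask]
        targets = np.array([float(income.get((muni, c), 0.0)) for c in inc_model.choice_set])
        draw = _assign_categorical(persons, mask, inc_model, targets, rng, config)
        persons.loc[mask, "income_class"] = np.array(inc_model.choice_set)[draw]

    # --- car ownership (zone car totals; minors own none) ----------------
    survey["car_cat"] = np.minimum(survey["n_cars"], 3).astype(str)
    car_model = train_choice_model(
        survey, ["age", "gender", "employment", "income_class", "household_size"],
        "car_cat", choice_set=["0", "1", "2", "3"])
    persons["n_cars"] = 0
    for zone_id, idx in persons.groupby("zone_id").groups.items():
        mask = persons.index.isin(idx) & (persons["age"] >= 18).to_numpy()
        if not mask.any():
            continue
        P = car_model.predict(persons.loc[mask])
        targets = _car_category_targets(P, float(zone_counts.at[zone_id, "n_cars"]))
        adjusted = fit_probabilities(P, targets, categories=car_model.choice_set,
                                     tol=config.ipf_tol, max_iter=config.ipf_max_iter)
        draw = sample_choices(adjusted, rng)
        persons.loc[mask, "n_cars"] = draw.astype(int)

    agg = "max" if config.household_cars == "max" else "sum"
    hh_cars = persons.groupby("HId")["n_cars"].agg(agg)
    households = households.copy()
    households["n_cars"] = households["HId"].map(hh_cars).fillna(0).astype(int)

    # map category code 3 back to the printed value ("3+" counts as 3 cars)
    persons["n_cars"] = persons["n_cars"].astype(int)
    return persons, households
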