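"""Shared categorical vocabularies and the age-band system.

The vocabularies mirror the published person / household / activity table
schemas: two genders, three marital states, five income classes bounded by
the national income quartiles up to 1 MSEK, five access modes and four
activity purposes (home, work, school, other).
"""

from __future__ import annotations

GENDERS = ["Male", "Female"]

# "age<18" marks minors; adults are "couple" or "single".
MARITAL = ["age<18", "couple", "single"]

INCOME_CLASSES = ["No", "Low", "Lower-middle", "Upper-middle", "High"]

# Income class boundaries in thousand SEK / year: {0, [1,180), [180,300),
# [300,420), [420,1000)}.
INCOME_CLASS_BOUNDS_KSEK: dict[str, tuple[int, int]] = {
    "No": (0, 0),
    "Low": (1, 180),
    "Lower-middle": (180, 300),
    "Upper-middle": (300, 420),
    "High": (420, 1000),
}

HOUSEHOLD_TYPES = ["single", "couple", "other"]

CAR_CATEGORIES = ["0", "1", "2", "3+"]

MODES = ["Car", "CarPassenger", "PublicTransport", "Bike", "Walking"]

# Activity purposes: internal single-letter codes and table spellings.
PURPOSES = ["H", "W", "S", "O"]
PURPOSE_NAMES = {"H": "Home", "W": "Work", "S": "School", "O": "Other"}
PURPOSE_CODES = {v: k for k, v in PURPOSE_NAMES.items()}

# Trip purposes used in supplied OD matrices (no school purpose exists there).
OD_PURPOSES = ["work", "business", "other", "private"]

BUILDING_USAGE_TYPES = ["detached_house", "apartment", "workplace", "school", "other"]
RESIDENTIAL_USAGE = ["detached_house", "apartment"]
BUILDING_TYPE_NAMES = {
    "detached_house": "Detached house",
    "apartment": "Apartment",
    "workplace": "Other",
    "school": "Other",
    "other": "Other",
}
# Usage type in which each non-home activity purpose takes place.
PURPOSE_TO_USAGE = {"W": "workplace", "S": "school", "O": "other"}

# Employment is only possible from this age (exclusive bound: age > 16).
MIN_EMPLOYMENT_AGE = 17

EMPLOYMENT_STUDENT_CATEGORIES = ["neither", "employed", "student", "both"]


def make_age_bands(width: int = 5, top: int = 95, max_age: int = 99) -> list[tuple[str, int, int]]:
    """Return (label, low, high) age bands: 0-4, 5-9, ..., ``top``+.

    ``high`` is inclusive; the open-ended top band is capped at ``max_age``
    so integer ages can be drawn uniformly within it.
    """
    bands = []
    for lo in range(0, top, width):
        hi = lo + width - 1
        bands.append((f"{lo}-{hi}", lo, hi))
    bands.append((f"{top}+", top, max_age))
    return bands


AGE_BANDS = make_age_bands()
AGE_BAND_LABELS = [b[0] for b in AGE_BANDS]
_BAND_BOUNDS = {label: (lo, hi) for label, lo, hi in AGE_BANDS}


def age_band_bounds(label: str) -> tuple[int, int]:
    return _BAND_BOUNDS[label]


def age_to_band(age: int) -> str:
    for label, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return label
    return AGE_BANDS[-1][0]
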