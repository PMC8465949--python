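"""Clinical instrument scoring and cohort table handling.

Implements the scoring formulas and diagnostic cutoffs for the instruments of
a paired pre/post functional-endoscopic-sinus-surgery cohort in chronic
rhinosinusitis (CRS):

* Lildholdt polyp score (per-side polyp grade 0-3, summed over both sides)
  and Lund-Kennedy endoscopy score (five findings graded 0-2 per side).
* Sniffin' Sticks TDI olfactory composite with the anosmia / hyposmia /
  normosmia cutoffs and the >= 5.5-point perceptible-improvement rule.
* SNOT-20 sinonasal quality-of-life subscores (primary / secondary nasal
  symptoms and general quality of life as percent of their item-block
  maximum) with the symptom-freedom cutoffs.

A cohort is a plain :class:`pandas.DataFrame` with ``patient_id`` and
``occasion`` columns ("baseline" / "post") plus one column per schema
variable; :func:`read_cohort` / :func:`write_cohort` round-trip it through
CSV with empty cells encoding missing values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Variable",
    "Schema",
    "default_schema",
    "Snot20Scores",
    "SymptomFreedom",
    "snot20_scores",
    "snot20_symptom_free",
    "olfactory_diagnosis",
    "perceptible_improvement",
    "endoscopic_totals",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "OCCASIONS",
    "CATEGORIES",
]

OCCASIONS = ("baseline", "post")
CATEGORIES = ("anatomy", "olfactory", "qol", "demographic")
SCALES = ("interval", "ordinal", "binary", "nominal")

# SNOT-20 item blocks (1-based item numbers) and normalizing constants.
SNOT_PRIMARY_ITEMS = (1, 2, 3, 5, 10)
SNOT_SECONDARY_ITEMS = (4, 6, 7, 8, 9, 12)
SNOT_GENERAL_ITEMS = (11, 13, 14, 15, 16, 17, 18, 19, 20)
_SNOT_PRIMARY_MAX = 25.0
_SNOT_SECONDARY_MAX = 30.0
_SNOT_GENERAL_MAX = 45.0

# Symptom-freedom cutoffs (strict less-than).
SNOT_TOTAL_CUTOFF = 12.0
SNOT_GENERAL_CUTOFF = 14.0
SNOT_PRIMARY_CUTOFF = 12.0
SNOT_SECONDARY_CUTOFF = 10.5

# TDI diagnostic cutoffs: anosmia < 16.5, hyposmia in [16.5, 30.5],
# normosmia > 30.5; an increase >= 5.5 points is subjectively perceptible.
TDI_ANOSMIA_CUTOFF = 16.5
TDI_NORMOSMIA_CUTOFF = 30.5
TDI_PERCEPTIBLE_DELTA = 5.5

LUND_KENNEDY_NO_FINDINGS_CUTOFF = 2


@dataclass(frozen=True)
class Variable:
    """Metadata for one cohort variable.

    ``support`` is a ``(low, high)`` pair for interval/ordinal variables and
    a tuple of admissible levels for binary/nominal ones. ``improves_when``
    states which direction of pre-to-post change counts as clinical
    improvement ("decreases", "increases" or "none").
    """

    name: str
    category: str
    scale: str
    support: tuple
    improves_when: str = "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for {self.name}")
        if self.improves_when not in ("decreases", "increases", "none"):
            raise ValueError(f"bad improves_when {self.improves_when!r} for {self.name}")

    @property
    def is_numeric(self) -> bool:
        return self.scale in ("interval", "ordinal")

    def in_support(self, value) -> bool:
        if pd.isna(value):
            return True
        if self.is_numeric:
            lo, hi = self.support
            return lo - 1e-9 <= float(value) <= hi + 1e-9
        return value in self.support or float(value) in self.support


class Schema:
    """Ordered collection of :class:`Variable` with name lookup."""

    def __init__(self, variables: Iterable[Variable]):
        self.variables = tuple(variables)
        self._by_name = {v.name: v for v in self.variables}
        if len(self._by_name) != len(self.variables):
            raise ValueError("duplicate variable names in schema")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[Variable]:
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Variable:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def by_category(self, category: str) -> list[Variable]:
        return [v for v in self.variables if v.category == category]

    def by_scale(self, *scales: str) -> list[Variable]:
        return [v for v in self.variables if v.scale in scales]

    def numeric_names(self) -> list[str]:
        return [v.name for v in self.variables if v.is_numeric]

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": v.name,
                "category": v.category,
                "scale": v.scale,
                "support": list(v.support),
                "improves_when": v.improves_when,
            }
            for v in self.variables
        ]

    @classmethod
    def from_dict(cls, entries: Sequence[dict]) -> "Schema":
        return cls(
            Variable(
                name=e["name"],
                category=e["category"],
                scale=e["scale"],
                support=tuple(e["support"]),
                improves_when=e.get("improves_when", "none"),
            )
            for e in entries
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(data)


def _v(name, category, scale, support, improves_when="none") -> Variable:
    return Variable(name, category, scale, tuple(support), improves_when)


def default_schema() -> Schema:
    """The d = 37 variable set: 3 anatomy, 8 olfactory, 14 quality-of-life
    and 12 demographic / concomitant-disease variables."""
    anatomy = [
        _v("lildholdt", "anatomy", "ordinal", (0, 6), "decreases"),
        _v("lund_kennedy", "anatomy", "ordinal", (0, 20), "decreases"),
        _v("eosinophilia", "anatomy", "ordinal", (0, 3), "none"),
    ]
    olfactory = [
        _v("tdi", "olfactory", "interval", (0, 48), "increases"),
        _v("olfactory_threshold", "olfactory", "interval", (0, 4), "increases"),
        _v("odor_discrimination", "olfactory", "interval", (0, 16), "increases"),
        _v("odor_identification", "olfactory", "interval", (0, 16), "increases"),
        _v("olfactory_rating_1", "olfactory", "ordinal", (0, 7), "increases"),
        _v("olfactory_rating_2", "olfactory", "ordinal", (1, 10), "increases"),
        _v("parosmia", "olfactory", "binary", (0, 1), "decreases"),
        _v("phantosmia", "olfactory", "binary", (0, 1), "decreases"),
    ]
    qol = [
        _v("primary_nasal_symptoms", "qol", "interval", (0, 100), "decreases"),
        _v("secondary_nasal_symptoms", "qol", "interval", (0, 100), "decreases"),
        _v("general_life_quality", "qol", "interval", (0, 100), "decreases"),
        _v("snot20_sum", "qol", "interval", (0, 100), "decreases"),
        _v("sf36_physical_functioning", "qol", "interval", (0, 100), "increases"),
        _v("sf36_role_physical", "qol", "interval", (0, 100), "increases"),
        _v("sf36_bodily_pain", "qol", "interval", (0, 100), "increases"),
        _v("sf36_general_health", "qol", "interval", (0, 100), "increases"),
        _v("sf36_vitality", "qol", "interval", (0, 100), "increases"),
        _v("sf36_social_functioning", "qol", "interval", (0, 100), "increases"),
        _v("sf36_role_emotional", "qol", "interval", (0, 100), "increases"),
        _v("sf36_mental_health", "qol", "interval", (0, 100), "increases"),
        _v("sf36_pcs", "qol", "interval", (-20, 130), "increases"),
        _v("sf36_mcs", "qol", "interval", (-20, 130), "increases"),
    ]
    demographic = [
        _v("age", "demographic", "interval", (0, 120)),
        _v("bmi", "demographic", "interval", (10, 70)),
        _v("sex", "demographic", "binary", (0, 1)),
        _v("steroid_use", "demographic", "binary", (0, 1)),
        _v("allergy_house_dust", "demographic", "binary", (0, 1)),
        _v("allergy_early_bloomers", "demographic", "binary", (0, 1)),
        _v("allergy_hay_fever", "demographic", "binary", (0, 1)),
        _v("allergy_grasses", "demographic", "binary", (0, 1)),
        _v("allergy_cat", "demographic", "binary", (0, 1)),
        _v("asthma_asa_triad", "demographic", "binary", (0, 1)),
        _v("asa_pseudoallergy", "demographic", "binary", (0, 1)),
        _v("asthma", "demographic", "binary", (0, 1)),
    ]
    return Schema(anatomy + olfactory + qol + demographic)


# ---------------------------------------------------------------------------
# Instrument scoring
# ---------------------------------------------------------------------------

class Snot20Scores(NamedTuple):
    primary_nasal: float
    secondary_nasal: float
    general_qol: float
    sum_score: int


class SymptomFreedom(NamedTuple):
    total: bool
    general: bool
    primary: bool
    secondary: bool


def snot20_scores(ratings: Sequence[int]) -> Snot20Scores:
    """Score the 20 SNOT-20 item ratings (each 0..5, 1-based item order).

    Subscores are the item-block sums expressed as percent of the block
    maximum: primary nasal = items 1,2,3,5,10 over 25; secondary nasal =
    items 4,6,7,8,9,12 over 30; general quality of life = items
    11,13,...,20 over 45.
    """
    ratings = list(ratings)
    if len(ratings) != 20:
        raise ValueError(f"expected 20 item ratings, got {len(ratings)}")
    for i, r in enumerate(ratings, start=1):
        if pd.isna(r) or int(r) != r or not 0 <= int(r) <= 5:
            raise ValueError(f"item {i} rating {r!r} not an integer in 0..5")
    ratings = [int(r) for r in ratings]

    def block(items: Sequence[int]) -> int:
        return sum(ratings[i - 1] for i in items)

    return Snot20Scores(
        primary_nasal=block(SNOT_PRIMARY_ITEMS) / _SNOT_PRIMARY_MAX * 100.0,
        secondary_nasal=block(SNOT_SECONDARY_ITEMS) / _SNOT_SECONDARY_MAX * 100.0,
        general_qol=block(SNOT_GENERAL_ITEMS) / _SNOT_GENERAL_MAX * 100.0,
        sum_score=sum(ratings),
    )


def snot20_symptom_free(scores: Snot20Scores) -> SymptomFreedom:
    """No-to-minor symptoms per criterion (strict less-than cutoffs)."""
    return SymptomFreedom(
        total=scores.sum_score < SNOT_TOTAL_CUTOFF,
        general=scores.general_qol < SNOT_GENERAL_CUTOFF,
        primary=scores.primary_nasal < SNOT_PRIMARY_CUTOFF,
        secondary=scores.secondary_nasal < SNOT_SECONDARY_CUTOFF,
    )


def olfactory_diagnosis(tdi: float) -> str:
    """Olfactory diagnosis from the TDI sum score.

    Anosmia below 16.5, hyposmia on the closed interval [16.5, 30.5],
    normosmia above 30.5.
    """
    if pd.isna(tdi) or tdi < 0:
        raise ValueError(f"TDI score must be >= 0, got {tdi!r}")
    if tdi < TDI_ANOSMIA_CUTOFF:
        return "anosmia"
    if tdi <= TDI_NORMOSMIA_CUTOFF:
        return "hyposmia"
    return "normosmia"


def perceptible_improvement(tdi_pre: float, tdi_post: float) -> bool:
    """Whether the TDI gain reaches the subjectively perceptible 5.5 points."""
    if pd.isna(tdi_pre) or pd.isna(tdi_post) or tdi_pre < 0 or tdi_post < 0:
        raise ValueError("TDI scores must be non-negative numbers")
    return tdi_post - tdi_pre >= TDI_PERCEPTIBLE_DELTA


def endoscopic_totals(
    per_side_polyp_grades: Sequence[int],
    per_side_lk_items: Sequence[Sequence[int]],
) -> tuple[int, int, bool]:
    """Sum per-side endoscopic gradings.

    ``per_side_polyp_grades``: polyp-size grade 0..3 for each of the two
    sides (Lildholdt total 0..6). ``per_side_lk_items``: for each of the two
    sides, the five Lund-Kennedy findings (polyps, edema, discharge,
    scarring, crusting) graded 0..2 (total 0..20). Returns
    ``(lildholdt, lund_kennedy, lk_no_findings)`` where the last flag is
    Lund-Kennedy < 2.
    """
    grades = list(per_side_polyp_grades)
    if len(grades) != 2 or any(int(g) != g or not 0 <= g <= 3 for g in grades):
        raise ValueError("need one polyp grade in 0..3 per side")
    sides = [list(items) for items in per_side_lk_items]
    if len(sides) != 2 or any(len(s) != 5 for s in sides):
        raise ValueError("need five Lund-Kennedy items per side")
    for s in sides:
        if any(int(x) != x or not 0 <= x <= 2 for x in s):
            raise ValueError("Lund-Kennedy items must be integers in 0..2")
    lildholdt = int(sum(grades))
    lund_kennedy = int(sum(sum(s) for s in sides))
    return lildholdt, lund_kennedy, lund_kennedy < LUND_KENNEDY_NO_FINDINGS_CUTOFF


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Validate a cohort table against the schema; returns the table.

    Checks: required columns present and no unknown variables; occasion
    values valid; at most one row per (patient, occasion); observed values
    inside each variable's support.
    """
    required = ["patient_id", "occasion"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks required columns {missing_cols}")
    unknown = [c for c in table.columns if c not in required and c not in schema]
    if unknown:
        raise ValueError(f"unknown variables not in schema: {unknown}")
    absent = [n for n in schema.names if n not in table.columns]
    if absent:
        raise ValueError(f"schema variables absent from table: {absent}")
    bad_occ = set(table["occasion"]) - set(OCCASIONS)
    if bad_occ:
        raise ValueError(f"invalid occasion labels {sorted(bad_occ)}; expected {OCCASIONS}")
    dup = table.duplicated(subset=["patient_id", "occasion"])
    if dup.any():
        pairs = table.loc[dup, ["patient_id", "occasion"]].values.tolist()
        raise ValueError(f"duplicated (patient, occasion) rows: {pairs[:5]}")
    for var in schema:
        col = table[var.name]
        ok = col.map(var.in_support)
        if not ok.all():
            bad = col[~ok].iloc[0]
            raise ValueError(f"value {bad!r} outside support of {var.name}")
    return table


def paired_patients(table: pd.DataFrame) -> list:
    """Patient ids present at both occasions (the completers)."""
    counts = table.groupby("patient_id")["occasion"].nunique()
    return sorted(counts.index[counts == 2])


def read_cohort(path, schema: Schema) -> pd.DataFrame:
    """Read a cohort CSV (comma-separated, UTF-8, empty cell = missing)."""
    table = pd.read_csv(path, dtype={"patient_id": str})
    for var in schema:
        if var.name not in table.columns:
            continue
        try:
            table[var.name] = pd.to_numeric(table[var.name])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable cell in column {var.name!r}: {exc}") from exc
    return validate_cohort(table, schema)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")
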