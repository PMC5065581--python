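"""Pineda clinical severity scale for Rett-spectrum patients.

Nine clinical features, each scored on its own small ordinal range (higher
= more severe); the total severity score is the plain sum of the nine, so
it runs from 3 (mildest possible: onset after 24 months, early sitting,
normal ambulation, no microcephaly/respiratory/epilepsy/hand involvement,
late stereotypies, preserved language) to 22 (all features at maximum).
Age is carried as metadata and never scored.

Feature coding:

====================  =====  ==========================================
feature               range  meaning of the extremes
====================  =====  ==========================================
onset_of_signs        1–3    1: > 24 months … 3: 0–12 months
microcephaly          0–1    0: absent; 1: present
sitting_alone         1–3    1: acquired < 8 months … 3: acquired, lost
ambulation            0–4    0: acquired < 18 months … 4: never acquired
respiratory_function  0–1    1: hyperventilation and/or apnea
epilepsy              0–2    0: absent … 2: uncontrolled or early
hand_use              0–3    0: acquired, conserved … 3: never acquired
stereotypies          1–3    1: onset > 10 years … 3: onset 18–36 months
language              0–2    0: preserved … 2: never acquired
====================  =====  ==========================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

__all__ = [
    "FEATURE_RANGES",
    "PinedaProfile",
    "score_pineda",
    "read_profiles",
    "summarize_cohort",
    "percentage",
    "MIN_TOTAL",
    "MAX_TOTAL",
]

FEATURE_RANGES: dict[str, tuple[int, int]] = {
    "onset_of_signs": (1, 3),
    "microcephaly": (0, 1),
    "sitting_alone": (1, 3),
    "ambulation": (0, 4),
    "respiratory_function": (0, 1),
    "epilepsy": (0, 2),
    "hand_use": (0, 3),
    "stereotypies": (1, 3),
    "language": (0, 2),
}

MIN_TOTAL = sum(lo for lo, _ in FEATURE_RANGES.values())  # 3
MAX_TOTAL = sum(hi for _, hi in FEATURE_RANGES.values())  # 22


class PinedaProfile(BaseModel):
    """One proband's nine scored clinical features plus (unscored) age."""

    onset_of_signs: int = Field(ge=1, le=3)
    microcephaly: int = Field(ge=0, le=1)
    sitting_alone: int = Field(ge=1, le=3)
    ambulation: int = Field(ge=0, le=4)
    respiratory_function: int = Field(ge=0, le=1)
    epilepsy: int = Field(ge=0, le=2)
    hand_use: int = Field(ge=0, le=3)
    stereotypies: int = Field(ge=1, le=3)
    language: int = Field(ge=0, le=2)
    age_years: float = Field(gt=0)
    proband: str = ""

    @property
    def features(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in FEATURE_RANGES}


def score_pineda(profile: PinedaProfile) -> int:
    """Total severity score: the sum of the nine feature scores."""
    return sum(profile.features.values())


def read_profiles(source: Union[str, Path]) -> list[PinedaProfile]:
    """Read a clinical-profile CSV (one row per proband; columns named after
    the nine features, plus ``age_years`` and optionally ``proband``).

    Validation is strict: a missing feature column or an out-of-range value
    is an error naming the offending feature; nothing is imputed.
    """
    df = pd.read_csv(source)
    missing = [c for c in FEATURE_RANGES if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV is missing feature column(s): {missing}")
    if "age_years" not in df.columns:
        raise ValueError("clinical CSV is missing the age_years column")
    profiles = []
    # row dicts keep per-column dtypes (iterrows would upcast to float)
    for row in df.to_dict(orient="records"):
        data = {c: row[c] for c in FEATURE_RANGES}
        data["age_years"] = row["age_years"]
        if "proband" in df.columns:
            data["proband"] = str(row["proband"])
        try:
            profiles.append(PinedaProfile(**data))
        except ValidationError as exc:
            bad = ", ".join(str(e["loc"][0]) for e in exc.errors())
            raise ValueError(
                f"invalid clinical profile for proband "
                f"{row.get('proband', '?')}: feature(s) {bad} out of range"
            ) from exc
    return profiles


def percentage(count: int, total: int) -> float:
    """Percentage rounded to one decimal, the cohort-reporting convention."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


#: Derived binary traits reported in cohort summaries.
TRAIT_PREDICATES = {
    "microcephaly": lambda p: p.microcephaly == 1,
    "epilepsy": lambda p: p.epilepsy >= 1,
    "never_walked": lambda p: p.ambulation == 4,
    "language_never_acquired": lambda p: p.language == 2,
    "breathing_dysfunction": lambda p: p.respiratory_function == 1,
    "stereotypies": lambda p: p.stereotypies >= 1,
}


def summarize_cohort(profiles: Sequence[PinedaProfile]) -> pd.DataFrame:
    """Prevalence of the derived clinical traits across a cohort.

    Returns a DataFrame with columns ``trait``, ``count``, ``denominator``,
    ``percent`` (one decimal). An empty cohort is an error, not an empty
    table.
    """
    if not profiles:
        raise ValueError("cannot summarize an empty cohort")
    n = len(profiles)
    rows = []
    for trait, pred in TRAIT_PREDICATES.items():
        count = sum(1 for p in profiles if pred(p))
        rows.append(
            {
                "trait": trait,
                "count": count,
                "denominator": n,
                "percent": percentage(count, n),
            }
        )
    return pd.DataFrame(rows)
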