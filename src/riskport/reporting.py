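"""Risk-communication rules: thermometer categories, doctor's-note matrix,
RCT arm allocation, uptake summaries, and per-participant portal payloads.

The 10-year absolute risk is binned into four thermometer categories
(0–5% low, 5–10% increased, 10–20% high, >20% very high; bounds are
left-closed/right-open with 20% itself counted as very high). The doctor's
note recommendation is a pure function of (risk category × age group):
under-50s with high risk are *encouraged* and very-high risk *recommended*
to see a physician; from 50 on, any risk above 10% is a recommendation.
The >75 group follows the 50–75 rules, with their risk evaluated at age 75.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .riskmodel import RiskEstimate
from .scv import NoteAction, SCVResult, select_scv_note

__all__ = [
    "RiskCategory",
    "AgeGroup",
    "Recommendation",
    "NOTE_MATRIX",
    "DoctorsNote",
    "RCTAssignment",
    "PortalPayload",
    "categorize_risk",
    "age_group",
    "select_doctors_note",
    "prs_population_percentile",
    "allocate_rct",
    "summarize_uptake",
    "average_risk_same_age",
    "build_portal_payload",
    "validate_payload",
]


class RiskCategory(str, enum.Enum):
    LOW = "low"
    INCREASED = "increased"
    HIGH = "high"
    VERY_HIGH = "very_high"


class AgeGroup(str, enum.Enum):
    UNDER_50 = "under_50"
    FROM_50_TO_75 = "from_50_to_75"
    OVER_75 = "over_75"


class Recommendation(str, enum.Enum):
    LIFESTYLE_ONLY = "lifestyle_only"
    ENCOURAGED_TO_SEE_PHYSICIAN = "encouraged_to_see_physician"
    RECOMMENDED_TO_SEE_PHYSICIAN = "recommended_to_see_physician"


#: Category bounds in percent: [0,5) low, [5,10) increased, [10,20) high,
#: [20,100] very high (left-closed/right-open; 20% is very high).
CATEGORY_BOUNDS = (
    (RiskCategory.LOW, 0.0, 5.0),
    (RiskCategory.INCREASED, 5.0, 10.0),
    (RiskCategory.HIGH, 10.0, 20.0),
    (RiskCategory.VERY_HIGH, 20.0, 100.0),
)

_OLDER = {
    RiskCategory.LOW: Recommendation.LIFESTYLE_ONLY,
    RiskCategory.INCREASED: Recommendation.LIFESTYLE_ONLY,
    RiskCategory.HIGH: Recommendation.RECOMMENDED_TO_SEE_PHYSICIAN,
    RiskCategory.VERY_HIGH: Recommendation.RECOMMENDED_TO_SEE_PHYSICIAN,
}

#: The full (age group → risk category → recommendation) matrix.
NOTE_MATRIX: dict[AgeGroup, dict[RiskCategory, Recommendation]] = {
    AgeGroup.UNDER_50: {
        RiskCategory.LOW: Recommendation.LIFESTYLE_ONLY,
        RiskCategory.INCREASED: Recommendation.LIFESTYLE_ONLY,
        RiskCategory.HIGH: Recommendation.ENCOURAGED_TO_SEE_PHYSICIAN,
        RiskCategory.VERY_HIGH: Recommendation.RECOMMENDED_TO_SEE_PHYSICIAN,
    },
    AgeGroup.FROM_50_TO_75: dict(_OLDER),
    AgeGroup.OVER_75: dict(_OLDER),
}


@dataclass(frozen=True)
class DoctorsNote:
    """Recommendation level plus the template the note text is rendered from.

    The engine decides only the recommendation code; localizable note text
    lives in external templates keyed by ``template_id``.
    """

    recommendation: Recommendation
    template_id: str
    includes_prevalent_disease_disclaimer: bool = False


@dataclass(frozen=True)
class RCTAssignment:
    """Disclosure arm: group 1 sees PRS + traditional risk at first release,
    group 2 traditional-only first (PRS added at the second release)."""

    sample_id: str
    group: int


def categorize_risk(r: RiskEstimate | float) -> RiskCategory:
    """Thermometer category of an absolute risk (probability in [0,1])."""
    prob = r.probability if isinstance(r, RiskEstimate) else float(r)
    if not 0.0 <= prob <= 1.0:
        raise ValidationError(f"probability must lie in [0,1], got {prob}")
    pct = prob * 100.0
    for cat, lo, hi in CATEGORY_BOUNDS:
        if lo <= pct < hi:
            return cat
    return RiskCategory.VERY_HIGH  # pct == 100 exactly


def age_group(age: float) -> AgeGroup:
    """<50 / 50–75 (inclusive) / >75."""
    if not age > 0:
        raise ValidationError(f"age must be positive, got {age}")
    if age < 50:
        return AgeGroup.UNDER_50
    if age <= 75:
        return AgeGroup.FROM_50_TO_75
    return AgeGroup.OVER_75


def select_doctors_note(
    cat: RiskCategory,
    ag: AgeGroup,
    prevalent_disease: bool = False,
) -> DoctorsNote:
    """Recommendation from the (risk category × age group) matrix."""
    rec = NOTE_MATRIX[ag][cat]
    return DoctorsNote(
        recommendation=rec,
        template_id=f"t2d_{cat.value}_{ag.value}",
        includes_prevalent_disease_disclaimer=bool(prevalent_disease),
    )


def prs_population_percentile(z: float) -> float:
    """Population percentile of a standardized score: 100·Φ(z)."""
    if not math.isfinite(z):
        raise ValidationError(f"z must be finite, got {z}")
    return float(100.0 * norm.cdf(z))


def allocate_rct(sample_ids: Sequence[str], seed: int) -> list[RCTAssignment]:
    """Seeded uniformly-random balanced split into two disclosure arms.

    Deterministic for a given seed; group sizes differ by at most one (the
    odd sample goes to group 2).
    """
    ids = list(sample_ids)
    if not ids:
        raise ValidationError("cannot allocate an empty cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n1 = len(ids) // 2
    group1 = {ids[i] for i in perm[:n1]}
    return [
        RCTAssignment(sample_id=s, group=1 if s in group1 else 2) for s in ids
    ]


def summarize_uptake(
    counts: Mapping[str, tuple[int, int]]
) -> dict[str, int]:
    """Percentages from (numerator, denominator) pairs.

    Rounded to the nearest integer, half away from zero. Numerators may not
    exceed denominators; zero denominators are an error.
    """
    out: dict[str, int] = {}
    for name, (num, den) in counts.items():
        if den <= 0:
            raise ValidationError(f"{name}: denominator must be positive, got {den}")
        if num < 0 or num > den:
            raise ValidationError(
                f"{name}: numerator {num} outside [0, denominator {den}]"
            )
        out[name] = int(math.floor(100.0 * num / den + 0.5))
    return out


def average_risk_same_age(
    ages: Sequence[float],
    risks: Sequence[float],
    age: float,
    band_years: float = 5.0,
) -> float:
    """Mean cohort risk in the participant's age band (5-year bands default)."""
    ages_arr = np.asarray(ages, dtype=float)
    risks_arr = np.asarray(risks, dtype=float)
    if ages_arr.shape != risks_arr.shape:
        raise ValidationError("ages and risks must have the same length")
    band = math.floor(age / band_years)
    mask = np.floor(ages_arr / band_years) == band
    if not mask.any():
        return float(np.mean(risks_arr))  # degenerate band: cohort mean
    return float(np.mean(risks_arr[mask]))


@dataclass
class PortalPayload:
    """Everything one participant sees in the portal, as one document.

    ``risk_at_60`` is present exactly when the participant is at most 50
    years old; for prevalent disease the risk stays present but the note
    carries the "no longer applies" disclaimer.
    """

    sample_id: str
    absolute_risk_10y: float
    risk_category: RiskCategory
    prs_z: float
    prs_population_percentile: float
    average_risk_same_age: float
    doctors_note: DoctorsNote
    scv_notes: list[dict]
    basis: str
    risk_at_60: float | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "absolute_risk_10y": self.absolute_risk_10y,
            "risk_category": self.risk_category.value,
            "prs_z": self.prs_z,
            "prs_population_percentile": self.prs_population_percentile,
            "average_risk_same_age": self.average_risk_same_age,
            "risk_at_60": self.risk_at_60,
            "doctors_note": {
                "recommendation": self.doctors_note.recommendation.value,
                "template_id": self.doctors_note.template_id,
                "includes_prevalent_disease_disclaimer": (
                    self.doctors_note.includes_prevalent_disease_disclaimer
                ),
            },
            "scv_notes": self.scv_notes,
            "basis": self.basis,
        }


#: Age at or below which the portal also shows the projected risk at 60.
RISK_AT_60_MAX_AGE = 50.0


def build_portal_payload(
    sample_id: str,
    age: float,
    risk: RiskEstimate,
    prs_z: float,
    average_risk: float,
    scv_results: Sequence[SCVResult] = (),
    risk_at_60: RiskEstimate | None = None,
    prevalent_disease: bool = False,
) -> PortalPayload:
    """Assemble one participant's portal document from component results."""
    for r in scv_results:
        if r.sample_id != sample_id:
            raise ValidationError(
                f"SCV result for {r.sample_id!r} mixed into payload of {sample_id!r}"
            )
    if age <= RISK_AT_60_MAX_AGE and risk_at_60 is None:
        raise ValidationError(
            f"participant {sample_id} is {age:.0f}; a projected risk at 60 is required"
        )
    cat = categorize_risk(risk)
    note = select_doctors_note(cat, age_group(age), prevalent_disease)
    scv_notes = []
    for r in scv_results:
        action = select_scv_note(r)
        if action is not NoteAction.NONE:
            scv_notes.append(
                {"scv_id": r.scv_id, "status": r.status.value, "action": action.value}
            )
    return PortalPayload(
        sample_id=sample_id,
        absolute_risk_10y=risk.probability,
        risk_category=cat,
        prs_z=float(prs_z),
        prs_population_percentile=prs_population_percentile(prs_z),
        average_risk_same_age=float(average_risk),
        doctors_note=note,
        scv_notes=scv_notes,
        basis=risk.basis,
        risk_at_60=(
            risk_at_60.probability if age <= RISK_AT_60_MAX_AGE else None
        ),
    )


_PAYLOAD_SCHEMA = {
    "sample_id": str,
    "absolute_risk_10y": float,
    "risk_category": str,
    "prs_z": float,
    "prs_population_percentile": float,
    "average_risk_same_age": float,
    "doctors_note": dict,
    "scv_notes": list,
    "basis": str,
}


def validate_payload(doc: Mapping) -> None:
    """Check a serialized payload against the shipped schema; raise on violation."""
    for key, typ in _PAYLOAD_SCHEMA.items():
        if key not in doc:
            raise ValidationError(f"payload missing field {key!r}")
        if not isinstance(doc[key], typ):
            raise ValidationError(
                f"payload field {key!r} has type {type(doc[key]).__name__}, "
                f"expected {typ.__name__}"
            )
    if not 0.0 <= doc["absolute_risk_10y"] <= 1.0:
        raise ValidationError("absolute_risk_10y outside [0,1]")
    if doc["risk_category"] not in {c.value for c in RiskCategory}:
        raise ValidationError(f"unknown risk category {doc['risk_category']!r}")
    if not 0.0 < doc["prs_population_percentile"] < 100.0:
        raise ValidationError("prs percentile outside (0,100)")
    if doc["basis"] not in ("with_prs", "traditional_only"):
        raise ValidationError(f"unknown basis {doc['basis']!r}")
    note = doc["doctors_note"]
    for key in ("recommendation", "template_id", "includes_prevalent_disease_disclaimer"):
        if key not in note:
            raise ValidationError(f"doctors_note missing field {key!r}")
    if note["recommendation"] not in {r.value for r in Recommendation}:
        raise ValidationError(f"unknown recommendation {note['recommendation']!r}")
    if "risk_at_60" in doc and doc["risk_at_60"] is not None:
        if not isinstance(doc["risk_at_60"], float) or not 0 <= doc["risk_at_60"] <= 1:
            raise ValidationError("risk_at_60 must be a probability")
    for item in doc["scv_notes"]:
        for key in ("scv_id", "status", "action"):
            if key not in item:
                raise ValidationError(f"scv note missing field {key!r}")
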