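"""Nutrient estimation, adequacy classification and cohort summaries.

The core mapping: a participant's mean daily food-group servings are
multiplied through the per-serving composition table (plus per-dose
supplement amounts when supplements are included) to give estimated daily
intakes of energy and the five key pregnancy micronutrients. Intakes are
then classified against the pregnancy Nutrient Reference Values into three
ordered adequacy classes — below the EAR, at or above the EAR but below
the RDI, and at or above the RDI — and food-group intakes are compared
with the AGTHE recommended daily servings.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .composition import (
    AgthTargets,
    CompositionTable,
    FoodGroup,
    NRVTable,
    Nutrient,
    ServingTarget,
    SupplementProduct,
    ValidationError,
)
from .records import DailyServings

__all__ = [
    "NutrientProfile",
    "AdequacyClass",
    "GroupSummary",
    "estimate_profile",
    "percent_of_ear",
    "classify_adequacy",
    "meets_target",
    "summarize_cohort",
]


@dataclass(frozen=True)
class NutrientProfile:
    """Estimated daily intake per nutrient for one participant.

    ``supplements_included`` records which analysis condition produced the
    profile (intake from food and supplements vs food only).
    """

    intakes: Mapping[Nutrient, float]
    supplements_included: bool
    participant_id: str = ""

    def __post_init__(self) -> None:
        for nutrient, value in self.intakes.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"{nutrient.value}: intake must be finite and >= 0, got {value}")

    def __getitem__(self, nutrient: Nutrient) -> float:
        return self.intakes.get(nutrient, 0.0)


@functools.total_ordering
class AdequacyClass(enum.Enum):
    """Ordinal intake-adequacy class against the EAR/RDI thresholds."""

    BELOW_EAR = 0
    EAR_TO_BELOW_RDI = 1
    AT_OR_ABOVE_RDI = 2

    def __lt__(self, other: "AdequacyClass") -> bool:
        if not isinstance(other, AdequacyClass):
            return NotImplemented
        return self.value < other.value

    @property
    def label(self) -> str:
        return {"BELOW_EAR": "<EAR", "EAR_TO_BELOW_RDI": "≥EAR to <RDI", "AT_OR_ABOVE_RDI": "≥RDI"}[self.name]


@dataclass(frozen=True)
class GroupSummary:
    """Cohort summary of one food group's daily servings."""

    group: FoodGroup
    mean: float
    sd: float  # sample SD (n-1); NaN for a single participant
    median: float
    iqr: tuple[float, float]
    n_meeting: int
    pct_meeting: float
    target: ServingTarget


def estimate_profile(
    servings: DailyServings,
    supplement_doses: Mapping[str, float],
    composition: CompositionTable,
    supplements: Sequence[SupplementProduct],
    include_supplements: bool,
    participant_id: str = "",
) -> NutrientProfile:
    """Estimate daily nutrient intake from mean servings and supplement doses.

    For each nutrient the estimate is the serving-weighted sum of the
    per-serving group composition, plus — when ``include_supplements`` is
    true — the dose-weighted sum of the per-dose supplement amounts.
    """
    by_id = {p.id: p for p in supplements}
    for pid in supplement_doses:
        if pid not in by_id:
            raise ValidationError(f"unknown supplement product {pid!r}")

    intakes: dict[Nutrient, float] = {}
    for nutrient in Nutrient:
        total = sum(
            servings[group] * composition.per_serving(group, nutrient) for group in FoodGroup
        )
        if include_supplements:
            total += sum(
                doses * by_id[pid].per_dose.get(nutrient, 0.0)
                for pid, doses in supplement_doses.items()
            )
        intakes[nutrient] = total
    return NutrientProfile(
        intakes=intakes, supplements_included=include_supplements, participant_id=participant_id
    )


def percent_of_ear(amount: float, nutrient: Nutrient, nrv: NRVTable, *, digits: int = 0) -> float:
    """Intake as a percentage of the nutrient's EAR, rounded for display.

    Default precision is the nearest integer percent (e.g. the 100 µg of
    folate in a 5 g serving of Vegemite is 19% of the 520 µg pregnancy EAR).
    """
    if nutrient is Nutrient.ENERGY or nutrient not in nrv.values:
        raise ValidationError(f"no EAR defined for {nutrient.value}")
    if amount < 0:
        raise ValidationError(f"amount must be >= 0, got {amount}")
    pct = 100.0 * amount / nrv.ear(nutrient)
    rounded = round(pct, digits)
    return int(rounded) if digits == 0 else rounded


def classify_adequacy(profile: NutrientProfile, nrv: NRVTable) -> dict[Nutrient, AdequacyClass]:
    """Classify each micronutrient intake against its EAR/RDI thresholds.

    Boundaries follow the class definitions literally: strictly below the
    EAR; at or above the EAR but strictly below the RDI; at or above the
    RDI. Energy is skipped (no EAR exists for it in this framework).
    Intakes are classified unrounded.
    """
    classes: dict[Nutrient, AdequacyClass] = {}
    for nutrient in nrv.nutrients:
        intake = profile[nutrient]
        if intake < nrv.ear(nutrient):
            classes[nutrient] = AdequacyClass.BELOW_EAR
        elif intake < nrv.rdi(nutrient):
            classes[nutrient] = AdequacyClass.EAR_TO_BELOW_RDI
        else:
            classes[nutrient] = AdequacyClass.AT_OR_ABOVE_RDI
    return classes


def meets_target(servings: float, target: ServingTarget) -> bool:
    """Whether a daily-serving value meets an AGTHE target.

    Threshold targets are met at or above the minimum; range targets are
    inclusive at both ends (so 2.5 servings of discretionary foods against
    the 0–2.5 range is met, 3.5 is not).
    """
    if servings < 0:
        raise ValidationError(f"servings must be >= 0, got {servings}")
    if target.is_range:
        return target.lo <= servings <= target.hi
    return servings >= target.lo


def summarize_cohort(
    servings_by_participant: Sequence[DailyServings], targets: AgthTargets
) -> list[GroupSummary]:
    """Cohort-level food-group summary: mean, SD, median, IQR, % meeting target.

    SD uses the n−1 denominator and is reported as NaN for a single
    participant; quartiles use linear interpolation between order
    statistics.
    """
    if not servings_by_participant:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(servings_by_participant)
    summaries = []
    for group in FoodGroup:
        values = np.array([s[group] for s in servings_by_participant], dtype=float)
        target = targets[group]
        n_meeting = int(sum(meets_target(v, target) for v in values))
        p25, median, p75 = np.percentile(values, [25, 50, 75])
        summaries.append(
            GroupSummary(
                group=group,
                mean=float(values.mean()),
                sd=float(values.std(ddof=1)) if n > 1 else float("nan"),
                median=float(median),
                iqr=(float(p25), float(p75)),
                n_meeting=n_meeting,
                pct_meeting=100.0 * n_meeting / n,
                target=target,
            )
        )
    return summaries
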