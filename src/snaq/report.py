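"""Per-participant feedback summaries and report rendering.

The feedback summary mirrors what a dietitian would relay back to a
participant: each food group's mean daily servings against its AGTHE
target (met or not, and by how many servings), and each key nutrient's
estimated intake against the pregnancy EAR and RDI with its adequacy
class and percentage of the EAR. Machine output is JSON with unrounded
numbers; rounding happens only in the text rendering (servings to 1
decimal, nutrient intakes to 2, percentages to integers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .composition import AgthTargets, FoodGroup, NRVTable, Nutrient, ServingTarget
from .engine import (
    AdequacyClass,
    NutrientProfile,
    classify_adequacy,
    meets_target,
    percent_of_ear,
)
from .records import DailyServings

__all__ = ["GroupFeedback", "NutrientFeedback", "FeedbackSummary", "build_feedback", "render_feedback_text"]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GroupFeedback:
    group: FoodGroup
    servings: float
    target: ServingTarget
    met: bool
    gap: float  # servings short of the minimum, or above the range ceiling; 0 when met


@dataclass(frozen=True)
class NutrientFeedback:
    nutrient: Nutrient
    intake: float
    ear: float
    rdi: float
    adequacy: AdequacyClass
    percent_of_ear: float


@dataclass(frozen=True)
class FeedbackSummary:
    participant_id: str
    groups: tuple[GroupFeedback, ...]
    nutrients: tuple[NutrientFeedback, ...]
    supplements_included: bool
    energy_kj: float


def _gap(servings: float, target: ServingTarget) -> float:
    if meets_target(servings, target):
        return 0.0
    if target.is_range and servings > target.hi:
        return servings - target.hi
    return target.lo - servings


def build_feedback(
    participant_id: str,
    servings: DailyServings,
    profile: NutrientProfile,
    targets: AgthTargets,
    nrv: NRVTable,
) -> FeedbackSummary:
    """Assemble the deterministic per-participant feedback summary."""
    groups = tuple(
        GroupFeedback(
            group=group,
            servings=servings[group],
            target=targets[group],
            met=meets_target(servings[group], targets[group]),
            gap=_gap(servings[group], targets[group]),
        )
        for group in FoodGroup
    )
    classes = classify_adequacy(profile, nrv)
    nutrients = tuple(
        NutrientFeedback(
            nutrient=nutrient,
            intake=profile[nutrient],
            ear=nrv.ear(nutrient),
            rdi=nrv.rdi(nutrient),
            adequacy=classes[nutrient],
            percent_of_ear=percent_of_ear(profile[nutrient], nutrient, nrv),
        )
        for nutrient in nrv.nutrients
    )
    return FeedbackSummary(
        participant_id=participant_id,
        groups=groups,
        nutrients=nutrients,
        supplements_included=profile.supplements_included,
        energy_kj=profile[Nutrient.ENERGY],
    )


_GROUP_NAMES = {
    FoodGroup.GRAINS: "Grains and cereals",
    FoodGroup.VEGETABLES: "Vegetables",
    FoodGroup.FRUIT: "Fruit",
    FoodGroup.MEAT: "Lean meat and alternatives",
    FoodGroup.DAIRY: "Dairy and alternatives",
    FoodGroup.FATS_OILS: "Unsaturated spreads and oils",
    FoodGroup.DISCRETIONARY: "Energy-dense, nutrient-poor foods",
}

_NUTRIENT_NAMES = {
    Nutrient.IRON: "Iron",
    Nutrient.CALCIUM: "Calcium",
    Nutrient.FOLATE_DFE: "Folate (DFE)",
    Nutrient.IODINE: "Iodine",
    Nutrient.ZINC: "Zinc",
}


def render_feedback_text(summary: FeedbackSummary) -> str:
    """Human-readable feedback, one line per food group and per nutrient."""
    condition = "food and supplements" if summary.supplements_included else "food only"
    lines = [
        f"Dietary feedback for {summary.participant_id} ({condition})",
        f"Estimated energy intake: {summary.energy_kj:.0f} kJ/day",
        "",
        "Food groups (mean servings/day vs AGTHE pregnancy target):",
    ]
    for g in summary.groups:
        status = "met" if g.met else (
            f"{g.gap:.1f} servings over the ceiling"
            if g.target.is_range and g.servings > (g.target.hi or 0)
            else f"{g.gap:.1f} servings short"
        )
        lines.append(
            f"  {_GROUP_NAMES[g.group]}: {g.servings:.1f} vs {g.target.describe()} — {status}"
        )
    lines.append("")
    lines.append("Key pregnancy nutrients (estimated daily intake vs EAR/RDI):")
    for nf in summary.nutrients:
        unit = nf.nutrient.unit
        lines.append(
            f"  {_NUTRIENT_NAMES[nf.nutrient]}: {nf.intake:.2f} {unit} "
            f"({nf.percent_of_ear:.0f}% of EAR {nf.ear:g} {unit}; RDI {nf.rdi:g} {unit}) "
            f"— {nf.adequacy.label}"
        )
    return "\n".join(lines)


def feedback_to_dict(summary: FeedbackSummary) -> dict:
    """JSON-ready feedback with unrounded values."""
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "participant_id": summary.participant_id,
        "supplements_included": summary.supplements_included,
        "energy_kj": summary.energy_kj,
        "groups": [
            {
                "group": g.group.value,
                "servings": g.servings,
                "target": g.target.describe(),
                "met": g.met,
                "gap": g.gap,
            }
            for g in summary.groups
        ],
        "nutrients": [
            {
                "nutrient": nf.nutrient.value,
                "intake": nf.intake,
                "unit": nf.nutrient.unit,
                "ear": nf.ear,
                "rdi": nf.rdi,
                "adequacy": nf.adequacy.name,
                "percent_of_ear": nf.percent_of_ear,
            }
            for nf in summary.nutrients
        ],
    }
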