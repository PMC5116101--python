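"""Estimate daily nutrient intake from a 3-day food-group record.

Builds one participant's record directly in code, averages it over the
recorded days, and runs the serving-to-nutrient estimation with and
without her daily prenatal supplement. Printed lines show the estimated
daily intake of energy and each key pregnancy nutrient, followed by the
adequacy class against the pregnancy EAR/RDI.
"""

from snaq import (
    DietaryRecord,
    FoodGroup,
    Nutrient,
    RecordItem,
    SupplementUse,
    classify_adequacy,
    default_composition,
    default_nrv,
    default_supplements,
    estimate_profile,
    mean_daily_servings,
    mean_daily_supplement_doses,
)

record = DietaryRecord(
    participant_id="demo",
    items=(
        RecordItem(day=1, group=FoodGroup.GRAINS, servings=4, occasion="breakfast+lunch"),
        RecordItem(day=1, group=FoodGroup.DAIRY, servings=2, occasion="breakfast"),
        RecordItem(day=1, group=FoodGroup.MEAT, servings=2, occasion="dinner"),
        RecordItem(day=2, group=FoodGroup.GRAINS, servings=5, occasion="all day"),
        RecordItem(day=2, group=FoodGroup.VEGETABLES, servings=3, occasion="dinner"),
        RecordItem(day=2, group=FoodGroup.FRUIT, servings=2, occasion="snacks"),
        RecordItem(day=3, group=FoodGroup.GRAINS, servings=4, occasion="all day"),
        RecordItem(day=3, group=FoodGroup.DISCRETIONARY, servings=3, occasion="dessert"),
    ),
    supplement_uses=tuple(
        SupplementUse(day=d, product_id="prenatal_multivitamin", doses=1) for d in (1, 2, 3)
    ),
)

composition = default_composition()
supplements = default_supplements()
nrv = default_nrv()

servings = mean_daily_servings(record)
doses = mean_daily_supplement_doses(record, supplements)

for include in (False, True):
    profile = estimate_profile(servings, doses, composition, supplements, include)
    classes = classify_adequacy(profile, nrv)
    label = "food + supplements" if include else "food only"
    print(f"\n{label}:")
    for nutrient in Nutrient:
        adequacy = classes[nutrient].label if nutrient in classes else "N/A"
        print(f"  {nutrient.value:>11}: {profile[nutrient]:8.2f} {nutrient.unit}/day  [{adequacy}]")
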