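"""Seeded synthetic cohorts with the statistical structure of the study.

The generator emulates a small pregnancy cohort keeping multi-day
food-group dietary records: per-group daily servings are drawn from
lognormal distributions parameterized by the cohort median and
interquartile range (right-skewed, nonnegative — the natural shape for
serving counts), a prenatal supplement is taken daily by a random subset
of participants, and a paired "reference method" nutrient profile is
formed from the brief method's food-level truth by applying a per-nutrient
multiplicative bias and lognormal noise. Everything is reproducible from a
single integer seed via numpy's PCG64 generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .composition import (
    CompositionTable,
    FoodGroup,
    Nutrient,
    SupplementProduct,
    ValidationError,
    default_composition,
    default_supplements,
)
from .engine import NutrientProfile, estimate_profile
from .records import DietaryRecord, RecordItem, SupplementUse, mean_daily_servings, mean_daily_supplement_doses
from .validity import AgreementResult, validity_table

__all__ = [
    "SyntheticConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "fit_lognormal_from_quartiles",
    "lognormal_quartiles",
    "recovery_experiment",
]

#: Cohort median (p25, p75) daily servings per food group — the observed
#: all-participant distribution the generator reproduces by default.
DEFAULT_GROUP_QUARTILES: dict[FoodGroup, tuple[float, float, float]] = {
    FoodGroup.GRAINS: (4.7, 3.6, 6.5),
    FoodGroup.VEGETABLES: (2.2, 1.2, 3.5),
    FoodGroup.FRUIT: (1.7, 0.9, 2.5),
    FoodGroup.MEAT: (1.9, 1.4, 2.9),
    FoodGroup.DAIRY: (1.8, 1.3, 2.7),
    FoodGroup.FATS_OILS: (2.0, 0.5, 3.0),
    FoodGroup.DISCRETIONARY: (3.5, 2.4, 3.9),
}

#: Default multiplicative reference-method bias per nutrient, set to the
#: ratio of the two methods' observed food-only medians (the reference
#: method reads energy lower and iron/folate higher than the brief tool).
DEFAULT_REFERENCE_BIAS: dict[Nutrient, float] = {
    Nutrient.ENERGY: 0.92,
    Nutrient.IRON: 1.24,
    Nutrient.CALCIUM: 0.91,
    Nutrient.FOLATE_DFE: 1.28,
    Nutrient.IODINE: 1.05,
    Nutrient.ZINC: 1.0,
}

_Z75 = stats.norm.ppf(0.75)  # 0.67448975...


def fit_lognormal_from_quartiles(median: float, p25: float, p75: float) -> tuple[float, float]:
    """Fit lognormal parameters (mu, sigma) from a median and quartiles.

    ``mu = ln(median)``; ``sigma = (ln p75 - ln p25) / (2 * z_0.75)`` with
    ``z_0.75`` the standard-normal upper quartile. The fitted distribution
    reproduces the median and the quartile ratio exactly; if the three
    inputs are the quartiles of an actual lognormal (log-symmetric about
    the median) all three are reproduced exactly.
    """
    if not (0.0 < p25 < median < p75):
        raise ValidationError(
            f"quartiles must satisfy 0 < p25 < median < p75, got ({p25}, {median}, {p75})"
        )
    mu = float(np.log(median))
    sigma = float((np.log(p75) - np.log(p25)) / (2.0 * _Z75))
    return mu, sigma


def lognormal_quartiles(mu: float, sigma: float) -> tuple[float, float, float]:
    """(median, p25, p75) of a lognormal(mu, sigma) distribution."""
    return (
        float(np.exp(mu)),
        float(np.exp(mu - _Z75 * sigma)),
        float(np.exp(mu + _Z75 * sigma)),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the study conditions: 25 participants, 3 recording days,
    serving distributions matching the observed cohort medians/IQRs, and a
    daily prenatal multivitamin taken by 60% of participants.
    ``reference_noise_sigma`` is the SD of the multiplicative lognormal
    error applied per nutrient to form the reference method's profile;
    ``reference_bias`` is its systematic multiplicative offset.
    ``zero_prob`` adds an optional point mass at zero servings per group
    (for subgroups whose lower quartile sits at zero).
    """

    n_participants: int = 25
    n_days: int = 3
    group_quartiles: Mapping[FoodGroup, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_QUARTILES)
    )
    zero_prob: Mapping[FoodGroup, float] = field(default_factory=dict)
    supplement_use_prob: float = 0.6
    supplement_product: SupplementProduct | None = None
    reference_noise_sigma: float = 0.15
    reference_bias: Mapping[Nutrient, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_BIAS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValidationError("n_participants and n_days must be >= 1")
        if not (0.0 <= self.supplement_use_prob <= 1.0):
            raise ValidationError("supplement_use_prob must lie in [0, 1]")
        if self.reference_noise_sigma < 0:
            raise ValidationError("reference_noise_sigma must be >= 0")
        for group, (median, p25, p75) in self.group_quartiles.items():
            fit_lognormal_from_quartiles(median, p25, p75)  # validates ordering
        for group, prob in self.zero_prob.items():
            if not (0.0 <= prob <= 1.0):
                raise ValidationError(f"{group.name}: zero_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedCohort:
    """One simulated cohort: records plus paired method profiles.

    ``snaq_*`` profiles come from running the generated records through
    the actual estimation pipeline; ``reference_*`` profiles are the
    noisy, biased reference-method observations of the same participants.
    """

    records: tuple[DietaryRecord, ...]
    snaq_food_only: tuple[NutrientProfile, ...]
    snaq_with_supplements: tuple[NutrientProfile, ...]
    reference_food_only: tuple[NutrientProfile, ...]
    reference_with_supplements: tuple[NutrientProfile, ...]


def simulate_cohort(
    config: SyntheticConfig, composition: CompositionTable | None = None
) -> SimulatedCohort:
    """Generate a seeded cohort of records and paired method profiles.

    Per participant: daily servings are drawn independently per group and
    day from the fitted lognormal (with an optional point mass at zero);
    supplement users take one dose of the configured product every day.
    The brief-method profiles are computed by the estimation engine from
    the generated records; each reference-method nutrient value is the
    food-level estimate times its bias times ``exp(sigma * Z)`` lognormal
    noise, with the supplement contribution added unperturbed (both
    methods see the same declared supplement doses).
    """
    rng = np.random.default_rng(config.seed)
    composition = composition if composition is not None else default_composition()
    product = (
        config.supplement_product
        if config.supplement_product is not None
        else default_supplements()[0]
    )

    params = {
        group: fit_lognormal_from_quartiles(*q) for group, q in config.group_quartiles.items()
    }

    records: list[DietaryRecord] = []
    snaq_food, snaq_with, ref_food, ref_with = [], [], [], []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        takes_supplement = rng.random() < config.supplement_use_prob
        items = []
        for day in range(1, config.n_days + 1):
            for group in FoodGroup:
                if group not in params:
                    continue
                if rng.random() < config.zero_prob.get(group, 0.0):
                    servings = 0.0
                else:
                    mu, sigma = params[group]
                    servings = float(rng.lognormal(mean=mu, sigma=sigma))
                items.append(RecordItem(day=day, group=group, servings=servings, occasion=f"day {day}"))
        uses = (
            tuple(
                SupplementUse(day=day, product_id=product.id, doses=1.0)
                for day in range(1, config.n_days + 1)
            )
            if takes_supplement
            else ()
        )
        record = DietaryRecord(participant_id=pid, items=tuple(items), supplement_uses=uses)
        records.append(record)

        servings = mean_daily_servings(record)
        doses = mean_daily_supplement_doses(record, [product])
        p_food = estimate_profile(servings, doses, composition, [product], False, pid)
        p_with = estimate_profile(servings, doses, composition, [product], True, pid)
        snaq_food.append(p_food)
        snaq_with.append(p_with)

        noise = {
            nutrient: float(np.exp(config.reference_noise_sigma * rng.standard_normal()))
            for nutrient in Nutrient
        }
        ref_intakes_food = {
            nutrient: p_food[nutrient] * config.reference_bias.get(nutrient, 1.0) * noise[nutrient]
            for nutrient in Nutrient
        }
        supplement_part = {n: p_with[n] - p_food[n] for n in Nutrient}
        ref_intakes_with = {n: ref_intakes_food[n] + supplement_part[n] for n in Nutrient}
        ref_food.append(NutrientProfile(ref_intakes_food, supplements_included=False, participant_id=pid))
        ref_with.append(NutrientProfile(ref_intakes_with, supplements_included=True, participant_id=pid))

    return SimulatedCohort(
        records=tuple(records),
        snaq_food_only=tuple(snaq_food),
        snaq_with_supplements=tuple(snaq_with),
        reference_food_only=tuple(ref_food),
        reference_with_supplements=tuple(ref_with),
    )


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    # 31-bit child seeds so every derived seed stays a small positive int
    state = np.random.SeedSequence(seed).generate_state(replicates, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def recovery_experiment(
    config: SyntheticConfig,
    replicates: int,
    nrv=None,
    composition: CompositionTable | None = None,
) -> dict:
    """Monte-Carlo distribution of the agreement statistics under a config.

    Runs ``simulate_cohort`` then the full validity table per replicate
    and summarizes rho and kappa per condition and nutrient: mean, SD,
    number of degenerate replicates, and the raw per-replicate values.
    """
    from .composition import default_nrv

    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    nrv = nrv if nrv is not None else default_nrv()
    composition = composition if composition is not None else default_composition()

    collected: dict[tuple[str, Nutrient], dict[str, list]] = {}
    for rep_seed in _replicate_seeds(config.seed, replicates):
        cohort = simulate_cohort(dataclasses.replace(config, seed=rep_seed), composition)
        results = validity_table(
            list(cohort.snaq_with_supplements) + list(cohort.snaq_food_only),
            list(cohort.reference_with_supplements) + list(cohort.reference_food_only),
            nrv,
        )
        for res in results:
            bucket = collected.setdefault(
                (res.condition, res.nutrient), {"rho": [], "kappa": [], "degenerate": 0}
            )
            if res.rho is not None:
                bucket["rho"].append(res.rho)
            if res.degenerate:
                bucket["degenerate"] += 1
            elif res.kappa is not None:
                bucket["kappa"].append(res.kappa)

    summary: dict = {}
    for (condition, nutrient), bucket in collected.items():
        rhos = np.array(bucket["rho"], dtype=float)
        kappas = np.array(bucket["kappa"], dtype=float)
        summary.setdefault(condition, {})[nutrient] = {
            "rho_mean": float(rhos.mean()) if rhos.size else None,
            "rho_sd": float(rhos.std(ddof=1)) if rhos.size > 1 else None,
            "kappa_mean": float(kappas.mean()) if kappas.size else None,
            "kappa_sd": float(kappas.std(ddof=1)) if kappas.size > 1 else None,
            "n_degenerate": bucket["degenerate"],
            "rhos": rhos.tolist(),
            "kappas": kappas.tolist(),
        }
    return summary
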