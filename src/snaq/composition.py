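"""Reference tables: food-group composition, supplements, NRVs and AGTHE targets.

The analysis rests on four small tables:

* a per-serving nutrient composition for each of the 7 AGTHE food groups
  (the bundled fixture is a documented stand-in with plausible group
  averages — replace it with your own table for real analyses);
* a supplement product table (per-dose nutrient amounts, with synthetic
  folic acid converted to dietary folate equivalents at load);
* the pregnancy Nutrient Reference Values (EAR and RDI per micronutrient);
* the AGTHE recommended daily servings per food group during pregnancy.

All loaders validate schema and invariants and fall back to the bundled
pregnancy defaults when no file is given.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "FoodGroup",
    "Nutrient",
    "GroupComposition",
    "CompositionTable",
    "SupplementProduct",
    "NRVTable",
    "ServingTarget",
    "AgthTargets",
    "SchemaError",
    "ValidationError",
    "EnergyBandWarning",
    "load_composition",
    "load_supplements",
    "load_nrv",
    "load_targets",
    "default_composition",
    "default_supplements",
    "default_nrv",
    "default_targets",
    "FOLIC_ACID_TO_DFE",
]


class SchemaError(ValueError):
    """A table is structurally wrong (missing/duplicate rows or columns)."""


class ValidationError(ValueError):
    """A table is structurally fine but carries an invalid value."""


class EnergyBandWarning(UserWarning):
    """Composition energy per serving outside the AGTHE standard-serving band."""


class FoodGroup(enum.Enum):
    """The seven AGTHE food groups (closed set)."""

    GRAINS = "grains"
    VEGETABLES = "vegetables"
    FRUIT = "fruit"
    MEAT = "meat"
    DAIRY = "dairy"
    FATS_OILS = "fats_oils"
    DISCRETIONARY = "discretionary"

    @classmethod
    def parse(cls, label: str) -> "FoodGroup":
        """Parse a free-text group label (case-insensitive, common synonyms)."""
        key = str(label).strip().lower().replace("-", " ").replace("_", " ")
        try:
            return _GROUP_ALIASES[key]
        except KeyError:
            raise SchemaError(f"unknown food group label: {label!r}") from None


_GROUP_ALIASES: dict[str, FoodGroup] = {}
for _g in FoodGroup:
    _GROUP_ALIASES[_g.value.replace("_", " ")] = _g
    _GROUP_ALIASES[_g.name.lower().replace("_", " ")] = _g
_GROUP_ALIASES.update(
    {
        "grains and cereals": FoodGroup.GRAINS,
        "grain": FoodGroup.GRAINS,
        "cereals": FoodGroup.GRAINS,
        "vegetable": FoodGroup.VEGETABLES,
        "fruits": FoodGroup.FRUIT,
        "lean meat": FoodGroup.MEAT,
        "lean meats and alternatives": FoodGroup.MEAT,
        "meat and alternatives": FoodGroup.MEAT,
        "dairy and alternatives": FoodGroup.DAIRY,
        "unsaturated spreads and oils": FoodGroup.FATS_OILS,
        "fats and oils": FoodGroup.FATS_OILS,
        "energy dense nutrient poor foods": FoodGroup.DISCRETIONARY,
        "energy dense, nutrient poor foods": FoodGroup.DISCRETIONARY,
        "discretionary foods": FoodGroup.DISCRETIONARY,
    }
)


class Nutrient(enum.Enum):
    """Energy plus the five key pregnancy micronutrients (closed set)."""

    ENERGY = "energy"
    IRON = "iron"
    CALCIUM = "calcium"
    FOLATE_DFE = "folate_dfe"
    IODINE = "iodine"
    ZINC = "zinc"

    @property
    def unit(self) -> str:
        return _NUTRIENT_UNITS[self]


_NUTRIENT_UNITS = {
    Nutrient.ENERGY: "kJ",
    Nutrient.IRON: "mg",
    Nutrient.CALCIUM: "mg",
    Nutrient.FOLATE_DFE: "µg",
    Nutrient.IODINE: "µg",
    Nutrient.ZINC: "mg",
}

#: CSV column name for each nutrient, shared by every tabular interface.
NUTRIENT_COLUMNS: dict[str, Nutrient] = {
    "energy_kj": Nutrient.ENERGY,
    "iron_mg": Nutrient.IRON,
    "calcium_mg": Nutrient.CALCIUM,
    "folate_dfe_ug": Nutrient.FOLATE_DFE,
    "iodine_ug": Nutrient.IODINE,
    "zinc_mg": Nutrient.ZINC,
}

#: AGTHE standard-serving energy bands (kJ per serving), one per group.
ENERGY_BANDS: dict[FoodGroup, tuple[float, float]] = {
    FoodGroup.GRAINS: (500.0, 500.0),
    FoodGroup.VEGETABLES: (100.0, 350.0),
    FoodGroup.FRUIT: (350.0, 350.0),
    FoodGroup.MEAT: (500.0, 600.0),
    FoodGroup.DAIRY: (500.0, 600.0),
    FoodGroup.FATS_OILS: (250.0, 250.0),
    FoodGroup.DISCRETIONARY: (600.0, 600.0),
}

#: µg dietary folate equivalents per µg synthetic folic acid (fortificant form).
FOLIC_ACID_TO_DFE = 1.7


@dataclass(frozen=True)
class GroupComposition:
    """Mean nutrient content of one standard AGTHE serving of one food group."""

    group: FoodGroup
    per_serving: Mapping[Nutrient, float]

    def __post_init__(self) -> None:
        for nutrient, amount in self.per_serving.items():
            if not (amount >= 0.0):
                raise ValidationError(
                    f"{self.group.name}: negative {nutrient.value} per serving ({amount})"
                )


@dataclass(frozen=True)
class CompositionTable:
    """One :class:`GroupComposition` per food group, covering all 7 groups."""

    rows: Mapping[FoodGroup, GroupComposition]

    def __post_init__(self) -> None:
        missing = [g.name for g in FoodGroup if g not in self.rows]
        if missing:
            raise SchemaError(f"composition table missing group(s): {', '.join(missing)}")

    def per_serving(self, group: FoodGroup, nutrient: Nutrient) -> float:
        return self.rows[group].per_serving.get(nutrient, 0.0)


@dataclass(frozen=True)
class SupplementProduct:
    """A micronutrient supplement: nutrient amounts per dose.

    ``folic_acid_ug`` is the synthetic folic acid per dose; it is converted
    to dietary folate equivalents and folded into ``per_dose`` at load time,
    so downstream code only ever sees total FOLATE_DFE.
    """

    id: str
    per_dose: Mapping[Nutrient, float]
    folic_acid_ug: float = 0.0

    def __post_init__(self) -> None:
        for nutrient, amount in self.per_dose.items():
            if not (amount >= 0.0):
                raise ValidationError(f"supplement {self.id}: negative {nutrient.value} ({amount})")
        if not (self.folic_acid_ug >= 0.0):
            raise ValidationError(f"supplement {self.id}: negative folic acid")


@dataclass(frozen=True)
class NRVTable:
    """Pregnancy EAR and RDI per micronutrient (energy has no EAR)."""

    values: Mapping[Nutrient, tuple[float, float]]  # nutrient -> (ear, rdi)

    def __post_init__(self) -> None:
        for nutrient, (ear, rdi) in self.values.items():
            if nutrient is Nutrient.ENERGY:
                raise ValidationError("energy has no EAR/RDI in this framework")
            if not (0.0 < ear < rdi):
                raise ValidationError(
                    f"{nutrient.value}: requires 0 < EAR < RDI, got EAR={ear}, RDI={rdi}"
                )

    def ear(self, nutrient: Nutrient) -> float:
        return self.values[nutrient][0]

    def rdi(self, nutrient: Nutrient) -> float:
        return self.values[nutrient][1]

    @property
    def nutrients(self) -> list[Nutrient]:
        return list(self.values)


@dataclass(frozen=True)
class ServingTarget:
    """An AGTHE daily-serving target: a minimum, or an inclusive [lo, hi] range."""

    lo: float
    hi: float | None = None  # None => threshold target (>= lo)

    def __post_init__(self) -> None:
        if self.lo < 0 or (self.hi is not None and self.hi < self.lo):
            raise ValidationError(f"invalid serving target: {self}")

    @property
    def is_range(self) -> bool:
        return self.hi is not None

    def describe(self) -> str:
        if self.is_range:
            return f"{self.lo:g}-{self.hi:g}"
        return f"≥{self.lo:g}"


@dataclass(frozen=True)
class AgthTargets:
    """AGTHE recommended daily servings per food group during pregnancy."""

    targets: Mapping[FoodGroup, ServingTarget]

    def __post_init__(self) -> None:
        missing = [g.name for g in FoodGroup if g not in self.targets]
        if missing:
            raise SchemaError(f"targets missing group(s): {', '.join(missing)}")

    def __getitem__(self, group: FoodGroup) -> ServingTarget:
        return self.targets[group]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("snaq").joinpath("data", name)))


def _check_energy_bands(table: CompositionTable, *, strict: bool, tolerance: float) -> None:
    for group, (lo, hi) in ENERGY_BANDS.items():
        energy = table.per_serving(group, Nutrient.ENERGY)
        lo_t, hi_t = lo * (1 - tolerance), hi * (1 + tolerance)
        if not (lo_t <= energy <= hi_t):
            msg = (
                f"{group.name}: energy {energy:g} kJ/serving outside the AGTHE band "
                f"{lo:g}-{hi:g} kJ (tolerance {tolerance:.0%})"
            )
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, EnergyBandWarning, stacklevel=3)


def load_composition(
    path: str | Path | None = None, *, strict: bool = False, energy_tolerance: float = 0.2
) -> CompositionTable:
    """Load a per-serving food-group composition table from CSV.

    Expected columns: ``group`` plus the six nutrient columns
    (``energy_kj, iron_mg, calcium_mg, folate_dfe_ug, iodine_ug, zinc_mg``).
    Energy per serving is checked against the AGTHE standard-serving bands:
    a warning by default, an error when ``strict`` is true.
    """
    path = _data_path("composition.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    required = {"group", *NUTRIENT_COLUMNS}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SchemaError(f"composition CSV missing column(s): {sorted(missing_cols)}")

    rows: dict[FoodGroup, GroupComposition] = {}
    for _, row in df.iterrows():
        group = FoodGroup.parse(row["group"])
        if group in rows:
            raise SchemaError(f"duplicate composition row for group {group.name}")
        per_serving = {}
        for col, nutrient in NUTRIENT_COLUMNS.items():
            value = float(row[col])
            if value < 0:
                raise ValidationError(f"{group.name}: negative {col} ({value})")
            per_serving[nutrient] = value
        rows[group] = GroupComposition(group=group, per_serving=per_serving)

    table = CompositionTable(rows=rows)
    _check_energy_bands(table, strict=strict, tolerance=energy_tolerance)
    return table


def load_supplements(
    path: str | Path | None = None, *, folic_acid_factor: float = FOLIC_ACID_TO_DFE
) -> list[SupplementProduct]:
    """Load supplement products from CSV (per-dose nutrient columns).

    An optional ``folic_acid_ug`` column carries synthetic folic acid per
    dose; it is converted to dietary folate equivalents with
    ``folic_acid_factor`` (default 1.7 µg DFE per µg folic acid) and added
    to the product's FOLATE_DFE.
    """
    path = _data_path("supplements.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    if df.empty:
        return []
    if "id" not in df.columns:
        raise SchemaError("supplement CSV missing 'id' column")

    products = []
    for _, row in df.iterrows():
        per_dose: dict[Nutrient, float] = {}
        for col, nutrient in NUTRIENT_COLUMNS.items():
            if col in df.columns and pd.notna(row[col]):
                value = float(row[col])
                if value < 0:
                    raise ValidationError(f"supplement {row['id']}: negative {col} ({value})")
                per_dose[nutrient] = value
        per_dose.setdefault(Nutrient.ENERGY, 0.0)
        folic = float(row["folic_acid_ug"]) if "folic_acid_ug" in df.columns and pd.notna(row.get("folic_acid_ug")) else 0.0
        if folic < 0:
            raise ValidationError(f"supplement {row['id']}: negative folic_acid_ug")
        per_dose[Nutrient.FOLATE_DFE] = per_dose.get(Nutrient.FOLATE_DFE, 0.0) + folic * folic_acid_factor
        products.append(SupplementProduct(id=str(row["id"]), per_dose=per_dose, folic_acid_ug=folic))
    return products


def load_nrv(path: str | Path | None = None) -> NRVTable:
    """Load EAR/RDI pairs from JSON, or return the pregnancy defaults.

    JSON shape: ``{"iron": {"ear": 22, "rdi": 27}, ...}`` keyed by nutrient
    column stem (iron, calcium, folate_dfe, iodine, zinc).
    """
    path = _data_path("nrv.json") if path is None else Path(path)
    raw = json.loads(Path(path).read_text())
    values: dict[Nutrient, tuple[float, float]] = {}
    for key, entry in raw.items():
        nutrient = Nutrient(key)
        values[nutrient] = (float(entry["ear"]), float(entry["rdi"]))
    return NRVTable(values=values)


def load_targets(path: str | Path | None = None) -> AgthTargets:
    """Load AGTHE serving targets from JSON, or return the pregnancy defaults.

    JSON shape: ``{"grains": {"min": 8.5}, "fats_oils": {"lo": 0, "hi": 2.5}, ...}``.
    """
    path = _data_path("agthe_targets.json") if path is None else Path(path)
    raw = json.loads(Path(path).read_text())
    targets: dict[FoodGroup, ServingTarget] = {}
    for key, entry in raw.items():
        group = FoodGroup.parse(key)
        if "min" in entry:
            targets[group] = ServingTarget(lo=float(entry["min"]))
        else:
            targets[group] = ServingTarget(lo=float(entry["lo"]), hi=float(entry["hi"]))
    return AgthTargets(targets=targets)


def default_composition(**kwargs) -> CompositionTable:
    return load_composition(None, **kwargs)


def default_supplements() -> list[SupplementProduct]:
    return load_supplements(None)


def default_nrv() -> NRVTable:
    return load_nrv(None)


def default_targets() -> AgthTargets:
    return load_targets(None)
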