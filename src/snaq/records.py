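"""Multi-day dietary records: parsing, validation and per-day averaging.

A record is a participant's list of (day, food group, servings) items plus
any supplement doses taken, captured over several non-consecutive days.
Records with too few distinct days are excluded before analysis; the rest
are collapsed to mean daily food-group servings (days with no items for a
group count as zero for that group) and mean daily supplement doses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .composition import FoodGroup, SchemaError, SupplementProduct, ValidationError

__all__ = [
    "RecordItem",
    "SupplementUse",
    "DietaryRecord",
    "DailyServings",
    "read_records",
    "valid_records",
    "mean_daily_servings",
    "mean_daily_supplement_doses",
]


@dataclass(frozen=True)
class RecordItem:
    """One food entry: ``servings`` AGTHE servings of ``group`` on ``day``."""

    day: int
    group: FoodGroup
    servings: float
    occasion: str = ""

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"day index must be >= 1, got {self.day}")
        if not (self.servings >= 0.0) or self.servings != self.servings or self.servings == float("inf"):
            raise ValidationError(f"servings must be finite and >= 0, got {self.servings}")


@dataclass(frozen=True)
class SupplementUse:
    """``doses`` doses of supplement ``product_id`` taken on ``day``."""

    day: int
    product_id: str
    doses: float

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"day index must be >= 1, got {self.day}")
        if not (self.doses >= 0.0):
            raise ValidationError(f"doses must be >= 0, got {self.doses}")


@dataclass(frozen=True)
class DietaryRecord:
    """All items and supplement uses one participant recorded."""

    participant_id: str
    items: tuple[RecordItem, ...]
    supplement_uses: tuple[SupplementUse, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "supplement_uses", tuple(self.supplement_uses))
        if not self.days_recorded:
            raise ValidationError(f"participant {self.participant_id}: record has no days")

    @property
    def days_recorded(self) -> frozenset[int]:
        """Distinct day indices with at least one item or supplement use."""
        return frozenset(i.day for i in self.items) | frozenset(u.day for u in self.supplement_uses)

    @property
    def n_days(self) -> int:
        return len(self.days_recorded)


@dataclass(frozen=True)
class DailyServings:
    """Mean daily AGTHE servings per food group for one participant."""

    servings: dict[FoodGroup, float]
    n_days: int

    def __getitem__(self, group: FoodGroup) -> float:
        return self.servings.get(group, 0.0)


def _records_from_frames(items_df: pd.DataFrame, uses_df: pd.DataFrame | None) -> list[DietaryRecord]:
    required = {"participant_id", "day", "group", "servings"}
    missing = required - set(items_df.columns)
    if missing:
        raise SchemaError(f"records table missing column(s): {sorted(missing)}")

    items_by_pid: dict[str, list[RecordItem]] = {}
    for i, row in items_df.iterrows():
        try:
            group = FoodGroup.parse(row["group"])
        except SchemaError as exc:
            raise SchemaError(f"row {i + 1}: {exc}") from None
        servings = float(row["servings"])
        if servings < 0:
            raise ValidationError(f"row {i + 1}: negative servings ({servings})")
        occasion = str(row["occasion"]) if "occasion" in items_df.columns and pd.notna(row.get("occasion")) else ""
        items_by_pid.setdefault(str(row["participant_id"]), []).append(
            RecordItem(day=int(row["day"]), group=group, servings=servings, occasion=occasion)
        )

    uses_by_pid: dict[str, list[SupplementUse]] = {}
    if uses_df is not None and not uses_df.empty:
        required_u = {"participant_id", "day", "product_id", "doses"}
        missing_u = required_u - set(uses_df.columns)
        if missing_u:
            raise SchemaError(f"supplement-use table missing column(s): {sorted(missing_u)}")
        for i, row in uses_df.iterrows():
            doses = float(row["doses"])
            if doses < 0:
                raise ValidationError(f"supplement-use row {i + 1}: negative doses ({doses})")
            uses_by_pid.setdefault(str(row["participant_id"]), []).append(
                SupplementUse(day=int(row["day"]), product_id=str(row["product_id"]), doses=doses)
            )

    pids = list(dict.fromkeys([*items_by_pid, *uses_by_pid]))
    return [
        DietaryRecord(
            participant_id=pid,
            items=tuple(items_by_pid.get(pid, ())),
            supplement_uses=tuple(uses_by_pid.get(pid, ())),
        )
        for pid in pids
    ]


def read_records(
    path: str | Path, supplement_uses_path: str | Path | None = None
) -> list[DietaryRecord]:
    """Read dietary records from a long-format CSV or JSON file.

    CSV columns: ``participant_id, day, occasion, group, servings``
    (``occasion`` optional); the optional companion supplement-use file has
    ``participant_id, day, product_id, doses``. A JSON file carries a list
    of objects with the same field names (optionally under top-level keys
    ``items`` and ``supplement_uses``). Returns one record per participant,
    item order preserved within each day.
    """
    path = Path(path)
    uses_df = None
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        if isinstance(raw, dict):
            items_df = pd.DataFrame(raw.get("items", []))
            if raw.get("supplement_uses"):
                uses_df = pd.DataFrame(raw["supplement_uses"])
        else:
            items_df = pd.DataFrame(raw)
    else:
        items_df = pd.read_csv(path)
    if supplement_uses_path is not None:
        uses_df = pd.read_csv(supplement_uses_path)
    return _records_from_frames(items_df, uses_df)


def valid_records(
    records: Sequence[DietaryRecord], min_days: int = 2
) -> tuple[list[DietaryRecord], list[tuple[DietaryRecord, str]]]:
    """Split records into analyzable and excluded by distinct days recorded.

    Records with fewer than ``min_days`` distinct day indices are excluded
    (the study design asks for multiple non-consecutive days; a single-day
    record cannot support a usual-intake average). Returns
    ``(kept, excluded)`` where each excluded entry carries its reason.
    """
    if min_days < 1:
        raise ValidationError(f"min_days must be >= 1, got {min_days}")
    kept, excluded = [], []
    for record in records:
        if record.n_days >= min_days:
            kept.append(record)
        else:
            excluded.append(
                (record, f"recorded {record.n_days} day(s), fewer than the required {min_days}")
            )
    return kept, excluded


def mean_daily_servings(record: DietaryRecord) -> DailyServings:
    """Mean servings/day per food group, averaged over the days recorded.

    The denominator is the number of distinct days the participant actually
    recorded; a day with no items for a group contributes zero servings of
    that group.
    """
    n_days = record.n_days
    totals = {group: 0.0 for group in FoodGroup}
    for item in record.items:
        totals[item.group] += item.servings
    return DailyServings(servings={g: t / n_days for g, t in totals.items()}, n_days=n_days)


def mean_daily_supplement_doses(
    record: DietaryRecord, products: Sequence[SupplementProduct] | None = None
) -> dict[str, float]:
    """Mean doses/day per supplement product over the days recorded.

    If ``products`` is given, every use must reference a known product id.
    """
    if products is not None:
        known = {p.id for p in products}
        for use in record.supplement_uses:
            if use.product_id not in known:
                raise ValidationError(
                    f"participant {record.participant_id}: unknown supplement product "
                    f"{use.product_id!r}"
                )
    n_days = record.n_days
    totals: dict[str, float] = {}
    for use in record.supplement_uses:
        totals[use.product_id] = totals.get(use.product_id, 0.0) + use.doses
    return {pid: t / n_days for pid, t in totals.items()}
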