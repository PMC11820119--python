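"""Apply a built GWP* database to dietary intake records.

Each record contributes ``amount_g / 1000 * gwp_value`` kg CO2e; totals
are additive over records, subjects and days.  Intakes of excluded foods
contribute zero but are counted and their grams totalled, so the
underestimation they introduce stays visible in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import (
    FoodRecord,
    InputValidationError,
    IntakeRecord,
    ResolvedGWP,
    UnresolvableError,
)


@dataclass(frozen=True)
class FootprintResult:
    """Total and itemized dietary climate footprint, kg CO2e."""

    total_kg_co2e: float
    per_food: pd.DataFrame  # food_code, amount_g, kg_co2e, excluded
    per_subject: pd.DataFrame  # subject_id, kg_co2e
    per_group: Optional[pd.DataFrame]  # major group rollup when foods given
    excluded_record_count: int
    excluded_amount_g: float


def compute_footprint(
    intakes: Sequence[IntakeRecord],
    resolved: Mapping[str, ResolvedGWP],
    foods: Optional[Mapping[str, FoodRecord]] = None,
) -> FootprintResult:
    """Compute the climate footprint of a set of intake records.

    Every intake food code must exist in the database; excluded foods are
    permitted and contribute 0.  Negative amounts and unknown codes are
    errors.
    """
    unknown = sorted({r.food_code for r in intakes} - set(resolved))
    if unknown:
        raise UnresolvableError(f"intake food codes not in database: {unknown}")
    for r in intakes:
        if r.amount_g < 0:
            raise InputValidationError(
                f"negative intake amount {r.amount_g} for {r.food_code}"
            )

    rows = []
    for r in intakes:
        res = resolved[r.food_code]
        excluded = res.excluded
        kg = 0.0 if excluded else (r.amount_g / 1000.0) * res.value
        rows.append(
            {
                "food_code": r.food_code,
                "subject_id": r.subject_id,
                "day": r.day,
                "amount_g": r.amount_g,
                "kg_co2e": kg,
                "excluded": excluded,
            }
        )
    detail = pd.DataFrame(
        rows,
        columns=["food_code", "subject_id", "day", "amount_g", "kg_co2e", "excluded"],
    )

    per_food = (
        detail.groupby("food_code", as_index=False)
        .agg(amount_g=("amount_g", "sum"), kg_co2e=("kg_co2e", "sum"),
             excluded=("excluded", "any"))
        if len(detail)
        else pd.DataFrame(columns=["food_code", "amount_g", "kg_co2e", "excluded"])
    )
    per_subject = (
        detail.groupby("subject_id", as_index=False).agg(kg_co2e=("kg_co2e", "sum"))
        if len(detail)
        else pd.DataFrame(columns=["subject_id", "kg_co2e"])
    )

    per_group = None
    if foods is not None:
        group_of = {code: food.major_code for code, food in foods.items()}
        if len(detail):
            detail_g = detail.assign(
                group_code=detail["food_code"].map(group_of)
            )
            per_group = detail_g.groupby("group_code", as_index=False).agg(
                amount_g=("amount_g", "sum"), kg_co2e=("kg_co2e", "sum")
            )
        else:
            per_group = pd.DataFrame(columns=["group_code", "amount_g", "kg_co2e"])

    excluded_rows = detail[detail["excluded"]] if len(detail) else detail
    return FootprintResult(
        total_kg_co2e=float(detail["kg_co2e"].sum()) if len(detail) else 0.0,
        per_food=per_food,
        per_subject=per_subject,
        per_group=per_group,
        excluded_record_count=int(len(excluded_rows)),
        excluded_amount_g=float(excluded_rows["amount_g"].sum())
        if len(excluded_rows)
        else 0.0,
    )
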