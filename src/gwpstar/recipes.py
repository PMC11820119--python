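"""Weighted-sum valuation of composite foods.

A composite food's value is the weight-proportional sum of its
ingredients' values::

    value = sum_i (weight_i / denominator) * gwp_i

Ingredients without a value ("unmatched") are dropped; under the default
``renormalize`` policy their weight leaves the denominator as well, so the
value is the weighted mean over the *matched* weight.  ``coverage`` — the
matched fraction of total recipe weight — records how much of the recipe
the value actually represents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .model import (
    GWPStarError,
    InputValidationError,
    RecipeCycleError,
    RecipeRow,
)

#: Resolver contract: ingredient id -> value in kg CO2e/kg, or None when
#: the ingredient has no match (exclusion signal).
IngredientResolver = Callable[[str], Optional[float]]


@dataclass(frozen=True)
class RecipeResolution:
    """Outcome of valuing one composite food."""

    parent_food_code: str
    included: tuple  # (ingredient id, weight_g, gwp value)
    excluded: tuple  # (ingredient id, weight_g)
    total_weight_g: float
    matched_weight_g: float
    value: Optional[float]

    @property
    def coverage(self) -> float:
        return self.matched_weight_g / self.total_weight_g

    @property
    def unmatched(self) -> bool:
        return self.value is None


def compute_composite_gwp(
    parent_food_code: str,
    rows: Sequence[tuple[str, float]],
    ingredient_resolver: IngredientResolver,
    policy: str = "renormalize",
) -> RecipeResolution:
    """Value a composite food from (ingredient id, weight g) rows.

    Returns an ``unmatched`` resolution (value None) when no ingredient
    could be valued, propagating the exclusion upward.
    """
    if not rows:
        raise InputValidationError(f"{parent_food_code}: empty recipe")
    if policy not in ("renormalize", "zero"):
        raise InputValidationError(f"unknown exclusion policy {policy!r}")

    included, dropped = [], []
    total_w = 0.0
    for ingredient, weight in rows:
        weight = float(weight)
        if weight <= 0:
            raise InputValidationError(
                f"{parent_food_code}: non-positive weight {weight} for "
                f"ingredient {ingredient!r}"
            )
        total_w += weight
        value = ingredient_resolver(ingredient)
        if value is None:
            dropped.append((ingredient, weight))
        else:
            included.append((ingredient, weight, float(value)))
    if total_w <= 0:
        raise InputValidationError(f"{parent_food_code}: zero total recipe weight")

    matched_w = sum(w for _, w, _ in included)
    if matched_w == 0:
        value = None
    else:
        denom = matched_w if policy == "renormalize" else total_w
        value = sum(w * g for _, w, g in included) / denom
    return RecipeResolution(
        parent_food_code=parent_food_code,
        included=tuple(included),
        excluded=tuple(dropped),
        total_weight_g=total_w,
        matched_weight_g=matched_w,
        value=value,
    )


#: grams per unit for description-derived amounts; water-like liquids are
#: taken at density 1 g/mL.
_UNIT_TO_G = {"g": 1.0, "kg": 1000.0, "mg": 0.001, "ml": 1.0, "l": 1000.0}


def recipe_from_description(
    components: Sequence[tuple],
    fraction_basis_g: float = 100.0,
    tol: float = 1e-6,
) -> list[tuple[str, float]]:
    """Turn described ingredient amounts into recipe rows in grams.

    ``components`` rows are ``(ingredient, amount, unit)`` with unit one of
    g/kg/mg/mL/L, or ``(ingredient, fraction, "fraction")`` for proportion
    declarations (which must sum to at most 1 and are scaled to
    ``fraction_basis_g``).  Mass amounts and fractions cannot be mixed.
    """
    if not components:
        raise InputValidationError("empty ingredient description")
    units = {str(c[2]).lower() for c in components}
    if "fraction" in units:
        if units != {"fraction"}:
            raise InputValidationError(
                "cannot mix fractional and mass amounts in one description"
            )
        fracs = [(str(c[0]), float(c[1])) for c in components]
        total = sum(f for _, f in fracs)
        if total > 1 + tol:
            raise InputValidationError(
                f"ingredient fractions sum to {total:.6g} > 1"
            )
        if any(f <= 0 for _, f in fracs):
            raise InputValidationError("ingredient fractions must be > 0")
        return [(name, f * fraction_basis_g) for name, f in fracs]

    rows = []
    for name, amount, unit in components:
        unit = str(unit).lower()
        if unit not in _UNIT_TO_G:
            raise InputValidationError(f"unknown unit {unit!r} for {name!r}")
        grams = float(amount) * _UNIT_TO_G[unit]
        if grams <= 0:
            raise InputValidationError(f"non-positive amount for {name!r}")
        rows.append((str(name), grams))
    return rows


def validate_acyclic(edges: Iterable[tuple[str, str]]) -> None:
    """Raise :class:`RecipeCycleError` if the parent->ingredient relation
    has a cycle; the error carries one cycle path."""
    graph = nx.DiGraph()
    graph.add_edges_from(edges)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        return
    raise RecipeCycleError([u for u, _ in cycle])


def rows_by_parent(recipes: Iterable[RecipeRow]) -> dict[str, list[tuple[str, float]]]:
    """Index recipe-table rows as parent -> [(ingredient, weight_g), ...]."""
    out: dict[str, list[tuple[str, float]]] = {}
    for row in recipes:
        out.setdefault(row.parent_food_code, []).append(
            (row.ingredient_food_code, row.ingredient_weight_g)
        )
    return out


def nutrient_consistency_report(
    rows: Sequence[tuple[str, float]],
    profiles: Mapping[str, Mapping[str, float]],
    target: Mapping[str, float],
    tolerance: float = 0.20,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Compare a recipe's mixed nutrient profile against its target food.

    Profiles are per 100 g.  The composite profile is the weight-
    proportional sum of ingredient profiles; the report gives the relative
    deviation ``|composite - target| / max(|target|, eps)`` per nutrient
    and flags those beyond ``tolerance``.  Nutrients missing from any
    ingredient profile or from the target are reported as not comparable
    rather than failing.
    """
    if not rows:
        raise InputValidationError("empty recipe")
    total_w = sum(w for _, w in rows)
    if total_w <= 0:
        raise InputValidationError("zero total recipe weight")

    nutrients: set[str] = set(target)
    for ing, _ in rows:
        nutrients.update(profiles.get(ing, {}))

    records = []
    for nutrient in sorted(nutrients):
        comparable = nutrient in target
        composite = 0.0
        for ing, w in rows:
            profile = profiles.get(ing)
            if profile is None or nutrient not in profile:
                comparable = False
                break
            composite += (w / total_w) * float(profile[nutrient])
        if comparable:
            tgt = float(target[nutrient])
            dev = abs(composite - tgt) / max(abs(tgt), eps)
            records.append(
                {
                    "nutrient": nutrient,
                    "composite": composite,
                    "target": tgt,
                    "rel_deviation": dev,
                    "flagged": dev > tolerance,
                    "comparable": True,
                }
            )
        else:
            records.append(
                {
                    "nutrient": nutrient,
                    "composite": float("nan"),
                    "target": float(target.get(nutrient, float("nan"))),
                    "rel_deviation": float("nan"),
                    "flagged": False,
                    "comparable": False,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "nutrient",
            "composite",
            "target",
            "rel_deviation",
            "flagged",
            "comparable",
        ],
    )
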