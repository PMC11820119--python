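"""Dispatch of foods to their assignment pathways.

Each food's curated match-spec entry names one of eleven pathways; the
resolver executes it against the reference table, the recipe table, and
the pool of already-resolved foods, recording stage/step provenance.  The
stage tabulation mirrors the accounting table such pipelines report:
per-step counts with half-up two-decimal percentages, stage subtotals,
and the matched total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .approx import GroupAverage, ProcessingFactor, apply_processing_factor, group_average
from .model import (
    BuildConfig,
    FoodRecord,
    GWPReferenceEntry,
    INLINE_RECIPE_METHODS,
    MatchMethod,
    MatchSpecEntry,
    ResolvedGWP,
    STAGE_STEP,
    STEP_ORDER,
    Unapproximable,
    UnresolvableError,
    percent_half_up,
)
from .recipes import RecipeResolution, compute_composite_gwp


@dataclass
class ResolutionContext:
    """Everything a single-food resolution may consult."""

    reference: Mapping[str, GWPReferenceEntry]
    recipe_rows: Mapping[str, Sequence[tuple[str, float]]]
    resolved: dict[str, ResolvedGWP]
    config: BuildConfig = field(default_factory=BuildConfig)
    group_items: Mapping[str, Sequence[str]] = field(default_factory=dict)
    processing_factors: Mapping[str, ProcessingFactor] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _reference_value(ctx: ResolutionContext, item_name: str) -> float:
    entry = ctx.reference.get(item_name)
    if entry is None:
        raise UnresolvableError(f"reference item not found: {item_name!r}")
    return entry.gwp_value


def _ingredient_resolver(ctx: ResolutionContext):
    """Resolve a recipe ingredient id: a food code already resolved, or a
    reference item name.  Excluded / unmatched foods signal exclusion."""

    def resolve(ingredient: str) -> Optional[float]:
        hit = ctx.resolved.get(ingredient)
        if hit is not None:
            return None if hit.excluded else hit.value
        entry = ctx.reference.get(ingredient)
        if entry is not None:
            return entry.gwp_value
        raise UnresolvableError(
            f"recipe ingredient {ingredient!r} is neither a resolved food "
            f"nor a reference item"
        )

    return resolve


def _from_recipe(food: FoodRecord, entry: MatchSpecEntry, rows, ctx) -> ResolvedGWP:
    stage, step = STAGE_STEP[entry.method]
    res: RecipeResolution = compute_composite_gwp(
        food.food_code,
        rows,
        _ingredient_resolver(ctx),
        policy=ctx.config.excluded_ingredient_policy,
    )
    if res.unmatched:
        return ResolvedGWP(
            food.food_code,
            None,
            "excluded",
            "excluded",
            coverage=None,
            note=f"no recipe ingredient could be valued ({step})",
        )
    if res.coverage < 1.0:
        ctx.warnings.append(
            f"{food.food_code}: recipe coverage {res.coverage:.3f} "
            f"({len(res.excluded)} unmatched ingredient(s) excluded)"
        )
    denom = (
        res.matched_weight_g
        if ctx.config.excluded_ingredient_policy == "renormalize"
        else res.total_weight_g
    )
    return ResolvedGWP(
        food.food_code,
        res.value,
        stage,
        step,
        coverage=res.coverage,
        provenance=tuple((ing, w / denom * g) for ing, w, g in res.included),
        note=entry.note,
    )


def resolve_food(
    food: FoodRecord, entry: MatchSpecEntry, ctx: ResolutionContext
) -> ResolvedGWP:
    """Execute one food's match-spec entry and return its resolution.

    Dependencies (recipe ingredients, similar-food targets) must already
    be present in ``ctx.resolved``; the database builder guarantees this
    by evaluating foods in dependency order.
    """
    method = entry.method
    stage, step = STAGE_STEP[method]

    if method is MatchMethod.EXCLUDED:
        return ResolvedGWP(
            food.food_code, None, "excluded", "excluded", coverage=None,
            note=entry.note or "no appropriate match",
        )

    if method in (MatchMethod.DIRECT, MatchMethod.APPROXIMATE):
        value = _reference_value(ctx, entry.target)
        return ResolvedGWP(
            food.food_code, value, stage, step,
            provenance=((entry.target, value),), note=entry.note,
        )

    if method is MatchMethod.RECIPE_FILE:
        rows = ctx.recipe_rows.get(food.food_code)
        if not rows:
            raise UnresolvableError(
                f"{food.food_code}: method recipe_file but no recipe rows"
            )
        return _from_recipe(food, entry, rows, ctx)

    if method in INLINE_RECIPE_METHODS:
        rows = [(str(i), float(w)) for i, w in entry.target]
        return _from_recipe(food, entry, rows, ctx)

    if method is MatchMethod.SIMILAR_FOOD:
        target = ctx.resolved.get(entry.target)
        if target is None:
            raise UnresolvableError(
                f"{food.food_code}: similar food {entry.target!r} not resolved"
            )
        if target.excluded:
            return ResolvedGWP(
                food.food_code, None, "excluded", "excluded", coverage=None,
                note=f"similar food {entry.target} is excluded",
            )
        return ResolvedGWP(
            food.food_code, target.value, stage, step,
            provenance=((entry.target, target.value),), note=entry.note,
        )

    if method is MatchMethod.GROUP_AVERAGE:
        group = entry.target or food.minor_code
        try:
            avg: GroupAverage = group_average(
                group,
                ctx.group_items,
                ctx.reference,
                scheme=ctx.config.scheme,
                fallback=ctx.config.group_fallback,
            )
        except Unapproximable as err:
            ctx.warnings.append(f"{food.food_code}: {err}")
            return ResolvedGWP(
                food.food_code, None, "excluded", "excluded", coverage=None,
                note=str(err),
            )
        if avg.level != "minor":
            ctx.warnings.append(
                f"{food.food_code}: group average fell back to "
                f"{avg.level} group {avg.group_code}"
            )
        return ResolvedGWP(
            food.food_code, avg.value, stage, step,
            provenance=tuple(
                (item, ctx.reference[item].gwp_value / len(avg.items))
                for item in avg.items
            ),
            note=entry.note or f"average of {avg.level} group {avg.group_code}",
        )

    if method is MatchMethod.PROCESSING_FACTOR:
        fresh_item, category = entry.target
        factor = ctx.processing_factors.get(category)
        if factor is None:
            ctx.warnings.append(
                f"{food.food_code}: no processing factor for {category!r}"
            )
            return ResolvedGWP(
                food.food_code, None, "excluded", "excluded", coverage=None,
                note=f"no processing factor available for {category}",
            )
        fresh_value = _reference_value(ctx, fresh_item)
        value = apply_processing_factor(fresh_value, factor)
        return ResolvedGWP(
            food.food_code, value, stage, step,
            provenance=((fresh_item, fresh_value), (f"{category} factor", factor.factor)),
            note=entry.note,
        )

    raise UnresolvableError(f"{food.food_code}: unknown method {method!r}")


_STAGE_LABELS = {1: "stage 1", 2: "stage 2", 3: "stage 3", "excluded": "excluded"}


@dataclass(frozen=True)
class StageTabulation:
    """Counts and half-up percentages per matching step and stage."""

    total: int
    step_counts: dict
    decimals: int = 2

    def count(self, step: str) -> int:
        return self.step_counts.get(step, 0)

    def percent(self, step: str) -> float:
        return percent_half_up(self.count(step), self.total, self.decimals)

    def stage_count(self, stage) -> int:
        return sum(
            n for step, n in self.step_counts.items()
            if STAGE_STEP[_STEP_TO_METHOD[step]][0] == stage
        )

    def stage_percent(self, stage) -> float:
        return percent_half_up(self.stage_count(stage), self.total, self.decimals)

    @property
    def matched_count(self) -> int:
        return self.total - self.count("excluded")

    @property
    def matched_percent(self) -> float:
        return percent_half_up(self.matched_count, self.total, self.decimals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in (1, 2, 3):
            rows.append(
                {
                    "row": _STAGE_LABELS[stage],
                    "count": self.stage_count(stage),
                    "percent": self.stage_percent(stage),
                }
            )
            for step in STEP_ORDER:
                if STAGE_STEP[_STEP_TO_METHOD[step]][0] == stage:
                    rows.append(
                        {
                            "row": f"  {step}",
                            "count": self.count(step),
                            "percent": self.percent(step),
                        }
                    )
        rows.append(
            {"row": "matched total", "count": self.matched_count,
             "percent": self.matched_percent}
        )
        rows.append(
            {"row": "excluded", "count": self.count("excluded"),
             "percent": self.percent("excluded")}
        )
        rows.append({"row": "total", "count": self.total, "percent": 100.0})
        return pd.DataFrame(rows, columns=["row", "count", "percent"])


_STEP_TO_METHOD = {step: method for method, (_, step) in STAGE_STEP.items()}


def tabulate_stages(resolved: Sequence[ResolvedGWP], decimals: int = 2) -> StageTabulation:
    """Tabulate a resolved database by matching step."""
    counts: dict[str, int] = {step: 0 for step in STEP_ORDER}
    for r in resolved:
        counts[r.step] += 1
    return StageTabulation(total=len(resolved), step_counts=counts, decimals=decimals)


def tabulation_from_counts(step_counts: Mapping[str, int], decimals: int = 2) -> StageTabulation:
    """Build a tabulation directly from per-step counts (e.g. a printed table)."""
    counts = {step: 0 for step in STEP_ORDER}
    for step, n in step_counts.items():
        if step not in counts:
            raise UnresolvableError(f"unknown step label {step!r}")
        counts[step] = int(n)
    return StageTabulation(total=sum(counts.values()), step_counts=counts,
                           decimals=decimals)
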