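"""Orchestration of full-database construction and summary reports.

The build resolves every food in dependency order (recipe ingredients and
similar-food targets before their dependents), derives the group-average
item mapping from the stage-1 matches, computes fruit/vegetable
processing factors once, and finishes with the stage tabulation and a
per-group mean ± SD summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .approx import ProcessingFactor, compute_processing_factor
from .model import (
    BuildConfig,
    FoodRecord,
    GWPReferenceEntry,
    INLINE_RECIPE_METHODS,
    InputValidationError,
    MatchMethod,
    MatchSpecEntry,
    RecipeRow,
    ResolvedGWP,
    UnresolvableError,
)
from .recipes import rows_by_parent, validate_acyclic
from .resolver import (
    ResolutionContext,
    StageTabulation,
    resolve_food,
    tabulate_stages,
)

_LEVEL_ATTR = {"major": "major_code", "sub_major": "sub_major_code", "minor": "minor_code"}


@dataclass
class BuildReport:
    """Human-readable account of one database build."""

    tabulation: StageTabulation
    processing_factors: dict[str, ProcessingFactor]
    warnings: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (code, reason)

    def to_text(self) -> str:
        lines = ["# Build report", "", "## Stage tabulation", ""]
        lines.append(self.tabulation.to_frame().to_string(index=False))
        lines.append("")
        lines.append("## Processing factors")
        if self.processing_factors:
            for cat, pf in sorted(self.processing_factors.items()):
                lines.append(f"- {cat}: {pf.factor:.4f} (from {len(pf.pairs)} pair(s))")
        else:
            lines.append("- none computed")
        lines.append("")
        lines.append(f"## Warnings ({len(self.warnings)})")
        lines.extend(f"- {w}" for w in self.warnings)
        lines.append("")
        lines.append(f"## Excluded foods ({len(self.excluded)})")
        lines.extend(f"- {code}: {reason}" for code, reason in self.excluded)
        return "\n".join(lines) + "\n"


@dataclass
class BuildResult:
    resolved: dict[str, ResolvedGWP]
    report: BuildReport

    @property
    def tabulation(self) -> StageTabulation:
        return self.report.tabulation


def _dependency_graph(
    foods: Mapping[str, FoodRecord],
    spec: Mapping[str, MatchSpecEntry],
    recipe_rows: Mapping[str, Sequence[tuple[str, float]]],
) -> nx.DiGraph:
    """Food-level dependency graph: an edge food -> dep means ``dep`` must
    resolve before ``food``.  Reference items are not nodes (always leaf)."""
    graph = nx.DiGraph()
    graph.add_nodes_from(foods)
    for code, entry in spec.items():
        if entry.method is MatchMethod.RECIPE_FILE:
            for ingredient, _ in recipe_rows.get(code, ()):
                if ingredient in foods:
                    graph.add_edge(code, ingredient)
        elif entry.method in INLINE_RECIPE_METHODS:
            for ingredient, _ in entry.target:
                if ingredient in foods:
                    graph.add_edge(code, ingredient)
        elif entry.method is MatchMethod.SIMILAR_FOOD:
            graph.add_edge(code, entry.target)
    return graph


def _validate_inputs(foods, spec, recipe_rows, reference):
    unspecified = sorted(set(foods) - set(spec))
    if unspecified:
        raise UnresolvableError(
            f"foods without a match-spec entry: {unspecified[:10]}"
            + (" ..." if len(unspecified) > 10 else "")
        )
    unknown = sorted(set(spec) - set(foods))
    if unknown:
        raise UnresolvableError(
            f"match-spec entries for unknown foods: {unknown[:10]}"
        )
    for code, entry in spec.items():
        if entry.method is MatchMethod.RECIPE_FILE and code not in recipe_rows:
            raise UnresolvableError(
                f"{code}: method recipe_file but food absent from recipe table"
            )
        if entry.method is MatchMethod.SIMILAR_FOOD and entry.target not in spec:
            raise UnresolvableError(
                f"{code}: similar food {entry.target!r} has no match-spec entry"
            )


def stage1_group_items(
    foods: Mapping[str, FoodRecord],
    spec: Mapping[str, MatchSpecEntry],
) -> dict[str, set[str]]:
    """Map every classification prefix (major, sub-major, minor) to the set
    of reference items used by stage-1 (direct/approximate) foods in it."""
    mapping: dict[str, set[str]] = {}
    for code, entry in spec.items():
        if entry.method in (MatchMethod.DIRECT, MatchMethod.APPROXIMATE):
            food = foods[code]
            for prefix in (food.major_code, food.sub_major_code, food.minor_code):
                mapping.setdefault(prefix, set()).add(entry.target)
    return mapping


def compute_processing_factors(
    pairs: Sequence[tuple[str, str, str]],
    reference: Mapping[str, GWPReferenceEntry],
) -> dict[str, ProcessingFactor]:
    """Per-category processing factors from (processed, fresh, category)
    item-name triples looked up in the reference table."""
    by_cat: dict[str, list] = {}
    for processed, fresh, category in pairs:
        for item in (processed, fresh):
            if item not in reference:
                raise UnresolvableError(
                    f"processing pair references unknown item {item!r}"
                )
        by_cat.setdefault(category, []).append(
            (processed, fresh, reference[processed].gwp_value,
             reference[fresh].gwp_value)
        )
    return {
        cat: compute_processing_factor(cat_pairs, cat)
        for cat, cat_pairs in by_cat.items()
    }


def build_database(
    foods: Mapping[str, FoodRecord],
    recipes: Sequence[RecipeRow],
    reference: Mapping[str, GWPReferenceEntry],
    match_spec: Mapping[str, MatchSpecEntry],
    config: Optional[BuildConfig] = None,
    processing_pairs: Sequence[tuple[str, str, str]] = (),
) -> BuildResult:
    """Resolve every food to a GWP* value or an exclusion.

    Deterministic: foods are visited in lexicographic topological order,
    so identical inputs give identical output (bit-for-bit on export).
    """
    config = config or BuildConfig()
    recipe_rows = rows_by_parent(recipes)
    _validate_inputs(foods, match_spec, recipe_rows, reference)
    validate_acyclic(
        (r.parent_food_code, r.ingredient_food_code) for r in recipes
    )

    graph = _dependency_graph(foods, match_spec, recipe_rows)
    try:
        order = list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(graph)]
        from .model import RecipeCycleError

        raise RecipeCycleError(cycle)
    # edges point dependent -> dependency, so resolve sinks first
    order.reverse()

    ctx = ResolutionContext(
        reference=reference,
        recipe_rows=recipe_rows,
        resolved={},
        config=config,
        group_items=stage1_group_items(foods, match_spec),
        processing_factors=compute_processing_factors(processing_pairs, reference),
    )
    for code in order:
        ctx.resolved[code] = resolve_food(foods[code], match_spec[code], ctx)

    excluded = [
        (code, ctx.resolved[code].note)
        for code in sorted(foods)
        if ctx.resolved[code].excluded
    ]
    report = BuildReport(
        tabulation=tabulate_stages(list(ctx.resolved.values()),
                                   decimals=config.round_decimals),
        processing_factors=ctx.processing_factors,
        warnings=ctx.warnings,
        excluded=excluded,
    )
    return BuildResult(resolved=ctx.resolved, report=report)


def summarize_by_group(
    resolved: Mapping[str, ResolvedGWP],
    foods: Mapping[str, FoodRecord],
    level: str = "major",
    sd_mode: str = "sample",
) -> pd.DataFrame:
    """Per-group n, mean and SD of food-level values (excluded foods
    omitted).  Groups whose every food is excluded appear with n = 0 and
    empty statistics.  Each food weighs equally (no consumption
    weighting); SD uses the n-1 denominator by default.
    """
    if level not in _LEVEL_ATTR:
        raise InputValidationError(f"unknown classification level {level!r}")
    if sd_mode not in ("sample", "population"):
        raise InputValidationError(f"unknown sd_mode {sd_mode!r}")
    ddof = 1 if sd_mode == "sample" else 0
    attr = _LEVEL_ATTR[level]

    values: dict[str, list[float]] = {}
    for code, food in foods.items():
        group = getattr(food, attr)
        values.setdefault(group, [])
        r = resolved.get(code)
        if r is not None and not r.excluded:
            values[group].append(r.value)

    rows = []
    for group in sorted(values):
        vals = np.asarray(values[group], dtype=float)
        n = len(vals)
        rows.append(
            {
                "group_code": group,
                "n": n,
                "mean": float(vals.mean()) if n else math.nan,
                "sd": float(vals.std(ddof=ddof)) if n > ddof else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group_code", "n", "mean", "sd"])
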