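"""Synthetic input bundles with known ground truth.

The real curated inputs of a GWP*-annotated food composition database —
the national food-details and recipe files, the published reference
values, and the expert match specification — are not redistributable, so
every pipeline stage is exercised against generated bundles instead: a
hierarchical 8-digit food classification spanning several major groups, a
reference table with log-normal values (a small fraction negated, as for
ruminant products whose methane emissions decline), acyclic multi-level
recipes, a planted mix of assignment pathways, and a controllable
fraction of unmatchable foods.

Ground truth is computed by a deliberately separate, non-recursive
bottom-up leaf expansion, so bugs in the pipeline's recursive resolution
cannot hide in shared code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io as gio
from .model import (
    FoodRecord,
    GWPReferenceEntry,
    InputValidationError,
    IntakeRecord,
    MatchMethod,
    MatchSpecEntry,
    RecipeRow,
    STAGE_STEP,
)

#: Default pathway mix, proportional to the step counts such national
#: mapping exercises report (roughly half of all foods valued from the
#: recipe file, ~a third matched directly or approximately, ~6%
#: approximated, ~4% unmatchable).
DEFAULT_STEP_MIX: dict[str, float] = {
    "direct": 883 / 5740,
    "approximate": 1139 / 5740,
    "recipe_file": 2709 / 5740,
    "description_recipe": 31 / 5740,
    "label_recipe": 104 / 5740,
    "nut_recipe": 24 / 5740,
    "similar_food": 258 / 5740,
    "online_recipe": 10 / 5740,
    "group_average": 326 / 5740,
    "processing_factor": 18 / 5740,
    "excluded": 238 / 5740,
}

_MAJORS = ("11", "12", "13", "14", "15", "16", "19", "21", "22", "24")
_NUTRIENTS = ("energy_kj", "protein_g", "fat_g", "carbohydrate_g")


@dataclass
class Bundle:
    """One complete synthetic input set for the pipeline."""

    foods: dict[str, FoodRecord]
    recipes: list[RecipeRow]
    reference: dict[str, GWPReferenceEntry]
    match_spec: dict[str, MatchSpecEntry]
    nutrient_profiles: dict[str, dict[str, float]]
    processing_pairs: list[tuple[str, str, str]]
    manifest: dict


@dataclass
class GroundTruth:
    """Expected pipeline output, recorded while generating the bundle."""

    values: dict[str, Optional[float]]  # None = excluded
    steps: dict[str, str]
    coverages: dict[str, Optional[float]]
    step_counts: dict[str, int]
    processing_factors: dict[str, float]

    def group_stats(
        self, foods: Mapping[str, FoodRecord], prefix_len: int = 2, ddof: int = 1
    ) -> dict[str, tuple[int, float, float]]:
        """Per-group (n, mean, sd) of matched ground-truth values."""
        groups: dict[str, list[float]] = {}
        for code, food in foods.items():
            groups.setdefault(food.food_code[:prefix_len], [])
            v = self.values.get(code)
            if v is not None:
                groups[food.food_code[:prefix_len]].append(v)
        out = {}
        for g, vals in sorted(groups.items()):
            arr = np.asarray(vals, dtype=float)
            n = len(arr)
            out[g] = (
                n,
                float(arr.mean()) if n else math.nan,
                float(arr.std(ddof=ddof)) if n > ddof else math.nan,
            )
        return out


def _allocate_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n foods across pathways."""
    methods = sorted(mix)
    total = sum(mix.values())
    if total <= 0:
        raise InputValidationError("step mix proportions must sum to a positive value")
    if abs(total - 1.0) > 1e-6:
        raise InputValidationError(f"step mix proportions sum to {total:.6g}, not 1")
    quotas = {m: mix[m] * n for m in methods}
    counts = {m: int(math.floor(quotas[m])) for m in methods}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        methods, key=lambda m: (-(quotas[m] - counts[m]), m)
    )
    for m in by_remainder[:leftover]:
        counts[m] += 1
    return counts


class _CodeFactory:
    """Unique hierarchical 8-digit codes: 2-digit major, 1-digit sub-major,
    2-digit minor, 3-digit serial."""

    def __init__(self, rng: np.random.Generator, majors: Sequence[str]):
        self.rng = rng
        self.majors = list(majors)
        self.serials: dict[str, int] = {}

    def new(self, major: Optional[str] = None, minor_prefix: Optional[str] = None) -> str:
        if minor_prefix is None:
            major = major or self.majors[self.rng.integers(len(self.majors))]
            sub = str(self.rng.integers(1, 10))
            minor = f"{self.rng.integers(1, 100):02d}"
            minor_prefix = major + sub + minor
        serial = self.serials.get(minor_prefix, 0) + 1
        if serial > 999:
            raise InputValidationError(
                f"minor group {minor_prefix} exhausted (>999 foods)"
            )
        self.serials[minor_prefix] = serial
        return f"{minor_prefix}{serial:03d}"


def _make_reference(
    rng: np.random.Generator,
    n_reference: int,
    negative_fraction: float,
    n_processing_pairs: int,
) -> tuple[dict[str, GWPReferenceEntry], list[tuple[str, str, str]]]:
    reference: dict[str, GWPReferenceEntry] = {}
    values = rng.lognormal(mean=-0.2, sigma=1.0, size=n_reference)
    n_neg = int(round(negative_fraction * n_reference))
    neg_idx = set(rng.choice(n_reference, size=n_neg, replace=False)) if n_neg else set()
    for i, v in enumerate(values):
        v = -float(v) if i in neg_idx else float(v)
        name = f"Item {i + 1:03d}"
        reference[name] = GWPReferenceEntry(name, v, source_tag="synthetic")
    reference["Water"] = GWPReferenceEntry("Water", 0.0, source_tag="synthetic")
    reference["Salt"] = GWPReferenceEntry("Salt", 0.06, source_tag="synthetic")

    pairs: list[tuple[str, str, str]] = []
    for category in ("fruit", "vegetable"):
        for k in range(n_processing_pairs):
            fresh_name = f"{category.capitalize()} {k + 1}, fresh"
            proc_name = f"{category.capitalize()} {k + 1}, processed"
            fresh_v = float(rng.lognormal(mean=-0.8, sigma=0.4))
            ratio = float(rng.lognormal(mean=0.4, sigma=0.25))
            reference[fresh_name] = GWPReferenceEntry(
                fresh_name, fresh_v, source_tag="synthetic"
            )
            reference[proc_name] = GWPReferenceEntry(
                proc_name, fresh_v * ratio, source_tag="synthetic"
            )
            pairs.append((proc_name, fresh_name, category))
    return reference, pairs


def _group_average_truth(
    code: str,
    stage1_items: Mapping[str, set],
    reference: Mapping[str, GWPReferenceEntry],
) -> Optional[float]:
    """Replicates the minor -> sub-major -> major fallback by direct
    arithmetic over the generator's stage-1 bookkeeping."""
    for prefix in (code[:5], code[:3], code[:2]):
        items = sorted(stage1_items.get(prefix, ()))
        if items:
            return sum(reference[i].gwp_value for i in items) / len(items)
    return None


def generate_bundle(
    n_foods: int = 200,
    step_mix: Optional[Mapping[str, float]] = None,
    recipe_depth: int = 3,
    max_ingredients: int = 6,
    n_reference: int = 232,
    negative_fraction: float = 0.02,
    excluded_fraction: Optional[float] = None,
    unmatched_ingredient_rate: float = 0.15,
    n_processing_pairs: int = 3,
    seed: int = 0,
) -> tuple[Bundle, GroundTruth]:
    """Generate a complete input bundle plus its expected resolution.

    ``step_mix`` gives the proportion of foods planted on each assignment
    pathway (default: the mix observed in national mapping exercises);
    ``excluded_fraction``, when given, overrides the mix's excluded share
    and rescales the rest.  Raises on infeasible parameter combinations
    (e.g. composite foods requested with no directly matchable foods).
    """
    if n_foods < 1:
        raise InputValidationError("n_foods must be >= 1")
    if recipe_depth < 1 or max_ingredients < 2:
        raise InputValidationError("need recipe_depth >= 1 and max_ingredients >= 2")

    mix = dict(step_mix or DEFAULT_STEP_MIX)
    unknown = set(mix) - {m.value for m in MatchMethod}
    if unknown:
        raise InputValidationError(f"unknown methods in step mix: {sorted(unknown)}")
    if excluded_fraction is not None:
        if not 0 <= excluded_fraction < 1:
            raise InputValidationError("excluded_fraction must be in [0, 1)")
        rest = sum(v for m, v in mix.items() if m != "excluded")
        scale = (1.0 - excluded_fraction) / rest
        mix = {m: v * scale for m, v in mix.items() if m != "excluded"}
        mix["excluded"] = excluded_fraction

    counts = _allocate_counts(mix, n_foods)
    n_stage1 = counts.get("direct", 0) + counts.get("approximate", 0)
    composite_methods = [
        "recipe_file", "description_recipe", "label_recipe",
        "nut_recipe", "online_recipe", "similar_food",
    ]
    n_dependent = sum(counts.get(m, 0) for m in composite_methods) + counts.get(
        "group_average", 0
    )
    if n_dependent and n_stage1 == 0:
        raise InputValidationError(
            "step mix plants dependent pathways but no direct/approximate foods"
        )
    if counts.get("recipe_file", 0) and n_stage1 < 2:
        raise InputValidationError("recipes need at least 2 directly matched foods")

    rng = np.random.default_rng(seed)
    n_majors = min(len(_MAJORS), max(5, n_foods // 25))
    majors = list(_MAJORS[:n_majors])
    codes = _CodeFactory(rng, majors)
    reference, processing_pairs = _make_reference(
        rng, n_reference, negative_fraction, n_processing_pairs
    )
    plain_items = sorted(
        n for n in reference if n not in ("Water", "Salt")
    )

    foods: dict[str, FoodRecord] = {}
    spec: dict[str, MatchSpecEntry] = {}
    recipes: list[RecipeRow] = []
    gt_values: dict[str, Optional[float]] = {}
    gt_steps: dict[str, str] = {}
    gt_cov: dict[str, Optional[float]] = {}
    # leaf composition per valued food: reference item -> weight fraction
    composition: dict[str, dict[str, float]] = {}
    depth: dict[str, int] = {}
    stage1_items: dict[str, set] = {}

    def add_food(method: str, code: str, name: str, target, note: str = "") -> str:
        foods[code] = FoodRecord(code, name, description=note)
        spec[code] = MatchSpecEntry(
            code, MatchMethod(method), target=target, note=note
        )
        gt_steps[code] = STAGE_STEP[MatchMethod(method)][1]
        return code

    # --- stage-1 and excluded foods (the ingredient pool) -------------
    for method in ("direct", "approximate"):
        for _ in range(counts.get(method, 0)):
            item = plain_items[rng.integers(len(plain_items))]
            code = codes.new()
            add_food(method, code, f"Food {code} ({item})", item)
            gt_values[code] = reference[item].gwp_value
            gt_cov[code] = 1.0
            composition[code] = {item: 1.0}
            depth[code] = 0
            for prefix in (code[:2], code[:3], code[:5]):
                stage1_items.setdefault(prefix, set()).add(item)

    excluded_pool: list[str] = []
    for _ in range(counts.get("excluded", 0)):
        code = codes.new()
        add_food("excluded", code, f"Food {code} (unmatchable)", None,
                 note="no appropriate match")
        gt_values[code] = None
        gt_cov[code] = None
        excluded_pool.append(code)

    valued_pool = [c for c in foods if gt_values[c] is not None]

    def composite_from(rows: list[tuple[str, float]]) -> tuple[float, float, dict]:
        """Flat-expansion oracle for one node: value, coverage, composition."""
        total_w = sum(w for _, w in rows)
        matched = [
            (ing, w) for ing, w in rows
            if (ing in composition) or (ing in reference)
        ]
        matched_w = sum(w for _, w in matched)
        comp: dict[str, float] = {}
        for ing, w in matched:
            frac = w / matched_w
            sub = composition.get(ing, {ing: 1.0})
            for leaf, leaf_frac in sub.items():
                comp[leaf] = comp.get(leaf, 0.0) + frac * leaf_frac
        value = sum(f * reference[leaf].gwp_value for leaf, f in comp.items())
        return value, matched_w / total_w, comp

    # --- composite pathways -------------------------------------------
    composite_slots: list[str] = []
    for m in composite_methods:
        composite_slots.extend([m] * counts.get(m, 0))
    rng.shuffle(composite_slots)

    for method in composite_slots:
        code = codes.new()
        if method == "similar_food":
            target = valued_pool[rng.integers(len(valued_pool))]
            add_food(method, code, f"Food {code} (like {target})", target)
            gt_values[code] = gt_values[target]
            gt_cov[code] = 1.0
            composition[code] = dict(composition[target])
            depth[code] = depth.get(target, 0)
        elif method == "recipe_file":
            eligible = [c for c in valued_pool if depth.get(c, 0) < recipe_depth]
            n_ing = int(rng.integers(2, max_ingredients + 1))
            n_ing = min(n_ing, len(eligible))
            picked = list(
                rng.choice(eligible, size=n_ing, replace=False)
            )
            if excluded_pool and rng.random() < unmatched_ingredient_rate:
                picked.append(excluded_pool[rng.integers(len(excluded_pool))])
            rows = [(ing, float(rng.uniform(5.0, 300.0))) for ing in picked]
            add_food(method, code, f"Food {code} (recipe)", None)
            recipes.extend(RecipeRow(code, ing, w) for ing, w in rows)
            value, cov, comp = composite_from(rows)
            gt_values[code], gt_cov[code], composition[code] = value, cov, comp
            depth[code] = 1 + max(depth.get(i, 0) for i in picked)
        else:  # inline recipe pathways
            n_ing = int(rng.integers(2, 6))
            picked = list(rng.choice(plain_items, size=n_ing, replace=False))
            if method == "description_recipe" and rng.random() < 0.5:
                picked.append("Water")
            if rng.random() < 0.3:
                shallow = [c for c in valued_pool if depth.get(c, 0) < recipe_depth]
                picked.append(shallow[int(rng.integers(len(shallow)))])
            if excluded_pool and rng.random() < unmatched_ingredient_rate:
                picked.append(excluded_pool[rng.integers(len(excluded_pool))])
            rows = [(ing, float(rng.uniform(5.0, 300.0))) for ing in picked]
            add_food(method, code, f"Food {code} ({method})", rows)
            value, cov, comp = composite_from(rows)
            gt_values[code], gt_cov[code], composition[code] = value, cov, comp
            depth[code] = 1 + max(
                (depth.get(i, 0) for i in picked if i in foods), default=0
            )
        if gt_values[code] is not None:
            valued_pool.append(code)

    # --- stage-3 pathways ---------------------------------------------
    stage1_codes = [
        c for c, e in spec.items()
        if e.method in (MatchMethod.DIRECT, MatchMethod.APPROXIMATE)
    ]
    for _ in range(counts.get("group_average", 0)):
        anchor = stage1_codes[int(rng.integers(len(stage1_codes)))]
        if rng.random() < 0.7:
            code = codes.new(minor_prefix=anchor[:5])
        else:
            code = codes.new(major=anchor[:2])
        add_food("group_average", code, f"Food {code} (group average)", None)
        value = _group_average_truth(code, stage1_items, reference)
        if value is None:  # no items even at the major level: becomes excluded
            gt_values[code] = None
            gt_cov[code] = None
            gt_steps[code] = "excluded"
        else:
            gt_values[code] = value
            gt_cov[code] = 1.0

    factor_truth = {}
    for category in ("fruit", "vegetable"):
        ratios = [
            reference[p].gwp_value / reference[f].gwp_value
            for p, f, c in processing_pairs
            if c == category and reference[f].gwp_value != 0
        ]
        if ratios:
            factor_truth[category] = sum(ratios) / len(ratios)
    fresh_by_cat = {
        cat: sorted(f for _, f, c in processing_pairs if c == cat)
        for cat in ("fruit", "vegetable")
    }
    for _ in range(counts.get("processing_factor", 0)):
        category = ("fruit", "vegetable")[int(rng.integers(2))]
        fresh = fresh_by_cat[category][
            int(rng.integers(len(fresh_by_cat[category])))
        ]
        code = codes.new()
        add_food(
            "processing_factor", code, f"Food {code} (processed {category})",
            (fresh, category),
        )
        gt_values[code] = reference[fresh].gwp_value * factor_truth[category]
        gt_cov[code] = 1.0

    # nutrient profiles for every reference item (per 100 g)
    profiles = {
        name: {
            "energy_kj": float(rng.uniform(100, 2500)),
            "protein_g": float(rng.uniform(0, 30)),
            "fat_g": float(rng.uniform(0, 40)),
            "carbohydrate_g": float(rng.uniform(0, 60)),
        }
        for name in sorted(reference)
    }

    step_counts = {STAGE_STEP[MatchMethod(m)][1]: 0 for m in mix}
    for step in gt_steps.values():
        step_counts[step] = step_counts.get(step, 0) + 1

    bundle = Bundle(
        foods=foods,
        recipes=recipes,
        reference=reference,
        match_spec=spec,
        nutrient_profiles=profiles,
        processing_pairs=processing_pairs,
        manifest={
            "seed": int(seed),
            "n_foods": int(n_foods),
            "recipe_depth": int(recipe_depth),
            "max_ingredients": int(max_ingredients),
            "n_reference": int(n_reference),
            "negative_fraction": float(negative_fraction),
            "unmatched_ingredient_rate": float(unmatched_ingredient_rate),
            "planted_counts": {k: int(v) for k, v in counts.items()},
        },
    )
    truth = GroundTruth(
        values=gt_values,
        steps=gt_steps,
        coverages=gt_cov,
        step_counts=step_counts,
        processing_factors=factor_truth,
    )
    return bundle, truth


def generate_intakes(
    bundle: Bundle,
    truth: GroundTruth,
    n_subjects: int = 10,
    records_per_subject: int = 20,
    seed: int = 0,
    excluded_rate: float = 0.1,
    amount_shape: float = 2.0,
    amount_scale: float = 75.0,
) -> tuple[list[IntakeRecord], dict]:
    """Draw intake records (gamma-distributed grams, mean ≈ 150 g per
    record) and their ground-truth footprint totals."""
    rng = np.random.default_rng(seed)
    matched = sorted(c for c, v in truth.values.items() if v is not None)
    excluded = sorted(c for c, v in truth.values.items() if v is None)
    if not matched:
        raise InputValidationError("bundle has no matched foods to consume")

    records: list[IntakeRecord] = []
    per_subject: dict[str, float] = {}
    for s in range(1, n_subjects + 1):
        sid = f"S{s:03d}"
        subtotal = 0.0
        for _ in range(records_per_subject):
            if excluded and rng.random() < excluded_rate:
                code = excluded[int(rng.integers(len(excluded)))]
            else:
                code = matched[int(rng.integers(len(matched)))]
            grams = float(rng.gamma(amount_shape, amount_scale))
            records.append(IntakeRecord(code, grams, subject_id=sid))
            v = truth.values[code]
            if v is not None:
                subtotal += grams / 1000.0 * v
        per_subject[sid] = subtotal
    return records, {
        "total": sum(per_subject.values()),
        "per_subject": per_subject,
    }


# ----------------------------------------------------------------------
# bundle persistence (CSV + JSON manifest), used by the CLI

def write_bundle(bundle: Bundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    pd.DataFrame(
        [
            {"food_code": f.food_code, "name": f.name, "description": f.description}
            for f in bundle.foods.values()
        ]
    ).to_csv(d / "food_details.csv", index=False)
    pd.DataFrame(
        [
            {
                "parent_food_code": r.parent_food_code,
                "ingredient_food_code": r.ingredient_food_code,
                "ingredient_weight_g": repr(r.ingredient_weight_g),
            }
            for r in bundle.recipes
        ],
        columns=["parent_food_code", "ingredient_food_code", "ingredient_weight_g"],
    ).to_csv(d / "recipes.csv", index=False)
    pd.DataFrame(
        [
            {"item_name": e.item_name, "gwp_value": repr(e.gwp_value),
             "source_tag": e.source_tag}
            for e in bundle.reference.values()
        ]
    ).to_csv(d / "gwp_reference.csv", index=False)
    gio.write_match_spec(bundle.match_spec, d / "match_spec.csv")
    pd.DataFrame(
        [
            {"ingredient_id": ing, "nutrient": nut, "per_100g": repr(v)}
            for ing, prof in bundle.nutrient_profiles.items()
            for nut, v in prof.items()
        ],
        columns=["ingredient_id", "nutrient", "per_100g"],
    ).to_csv(d / "nutrient_profiles.csv", index=False)
    pd.DataFrame(
        bundle.processing_pairs,
        columns=["processed_item", "fresh_item", "category"],
    ).to_csv(d / "processing_pairs.csv", index=False)
    (d / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))


def read_bundle(directory) -> Bundle:
    d = Path(directory)
    manifest = {}
    if (d / "manifest.json").exists():
        manifest = json.loads((d / "manifest.json").read_text())
    pairs_path = d / "processing_pairs.csv"
    profiles_path = d / "nutrient_profiles.csv"
    return Bundle(
        foods=gio.read_food_details(d / "food_details.csv"),
        recipes=gio.read_recipes(d / "recipes.csv"),
        reference=gio.read_gwp_reference(d / "gwp_reference.csv"),
        match_spec=gio.read_match_spec(d / "match_spec.csv"),
        nutrient_profiles=(
            gio.read_nutrient_profiles(profiles_path)
            if profiles_path.exists()
            else {}
        ),
        processing_pairs=(
            gio.read_processing_pairs(pairs_path) if pairs_path.exists() else []
        ),
        manifest=manifest,
    )


def write_intakes(records: Sequence[IntakeRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "food_code": r.food_code,
                "amount_g": repr(r.amount_g),
                "subject_id": r.subject_id,
                "day": r.day,
            }
            for r in records
        ],
        columns=["food_code", "amount_g", "subject_id", "day"],
    ).to_csv(path, index=False)
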