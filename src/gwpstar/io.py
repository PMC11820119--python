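"""CSV readers and writers for the pipeline's tables.

All inputs are UTF-8 CSV with a header row.  Food codes are read as
strings (leading zeros are significant).  Column contracts:

====================  =====================================================
food details          food_code, name, description
GWP* reference        item_name, gwp_value[, source_tag]
recipe table          parent_food_code, ingredient_food_code,
                      ingredient_weight_g
match spec            food_code, method, target[, note]  (structured
                      targets — inline ingredient lists and processing
                      pairs — are JSON-encoded in the target cell)
nutrient profiles     ingredient_id, nutrient, per_100g   (long format)
intakes               food_code, amount_g[, subject_id, day]
processing pairs      processed_item, fresh_item, category
====================  =====================================================

The output database carries full provenance; values are rounded half-up
to two decimals at export only — internal computation keeps full float
precision so rounding error cannot compound through nested recipes.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import (
    BuildConfig,
    ClassificationScheme,
    DEFAULT_SCHEME,
    FoodRecord,
    GWPReferenceEntry,
    INLINE_RECIPE_METHODS,
    InputValidationError,
    IntakeRecord,
    MatchMethod,
    MatchSpecEntry,
    RecipeRow,
    ResolvedGWP,
    round_half_up,
)

PathLike = Union[str, Path]


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise InputValidationError(f"input file not found: {path}")
    except pd.errors.EmptyDataError:
        raise InputValidationError(f"{path}: empty file (missing header)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing column(s) {missing}")
    return df


def _float(raw: str, path, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise InputValidationError(
            f"{path} row {row}: non-numeric {col} {raw!r}"
        )


def read_food_details(
    path: PathLike, scheme: ClassificationScheme = DEFAULT_SCHEME
) -> dict[str, FoodRecord]:
    """Read the food-details table; returns records keyed by food code."""
    df = _read_csv(path, ["food_code", "name"])
    foods: dict[str, FoodRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        code = row.food_code.strip()
        try:
            record = FoodRecord(
                food_code=code,
                name=row.name,
                description=getattr(row, "description", ""),
                scheme=scheme,
            )
        except InputValidationError as err:
            raise InputValidationError(f"{path} row {i}: {err}")
        if code in foods:
            raise InputValidationError(f"{path} row {i}: duplicate food_code {code}")
        foods[code] = record
    return foods


def read_gwp_reference(path: PathLike) -> dict[str, GWPReferenceEntry]:
    """Read the GWP* reference table, keyed by item name."""
    df = _read_csv(path, ["item_name", "gwp_value"])
    out: dict[str, GWPReferenceEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = row.item_name.strip()
        if not name:
            raise InputValidationError(f"{path} row {i}: empty item_name")
        if name in out:
            raise InputValidationError(f"{path} row {i}: duplicate item_name {name!r}")
        value = _float(row.gwp_value, path, i, "gwp_value")
        if not math.isfinite(value):
            raise InputValidationError(f"{path} row {i}: non-finite gwp_value")
        out[name] = GWPReferenceEntry(
            item_name=name, gwp_value=value,
            source_tag=getattr(row, "source_tag", ""),
        )
    return out


def read_recipes(path: PathLike) -> list[RecipeRow]:
    """Read the parent->ingredient recipe table."""
    df = _read_csv(
        path, ["parent_food_code", "ingredient_food_code", "ingredient_weight_g"]
    )
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rows.append(
                RecipeRow(
                    parent_food_code=row.parent_food_code.strip(),
                    ingredient_food_code=row.ingredient_food_code.strip(),
                    ingredient_weight_g=_float(
                        row.ingredient_weight_g, path, i, "ingredient_weight_g"
                    ),
                )
            )
        except InputValidationError as err:
            raise InputValidationError(f"{path} row {i}: {err}")
    return rows


def _parse_target(method: MatchMethod, raw: str, path, row: int):
    raw = raw.strip()
    if method in (MatchMethod.RECIPE_FILE, MatchMethod.EXCLUDED):
        return None
    if method is MatchMethod.GROUP_AVERAGE:
        return raw or None
    if method in INLINE_RECIPE_METHODS or method is MatchMethod.PROCESSING_FACTOR:
        try:
            parsed = json.loads(raw)
        except json.JSONDecodeError:
            raise InputValidationError(
                f"{path} row {row}: target for {method.value} must be JSON"
            )
        if method is MatchMethod.PROCESSING_FACTOR:
            return tuple(parsed)
        return [(str(i), float(w)) for i, w in parsed]
    return raw


def _serialize_target(entry: MatchSpecEntry) -> str:
    t = entry.target
    if t is None:
        return ""
    if entry.method in INLINE_RECIPE_METHODS:
        return json.dumps([[i, w] for i, w in t])
    if entry.method is MatchMethod.PROCESSING_FACTOR:
        return json.dumps(list(t))
    return str(t)


def read_match_spec(path: PathLike) -> dict[str, MatchSpecEntry]:
    """Read the curated match specification, keyed by food code."""
    df = _read_csv(path, ["food_code", "method", "target"])
    out: dict[str, MatchSpecEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        code = row.food_code.strip()
        try:
            method = MatchMethod(row.method.strip())
        except ValueError:
            raise InputValidationError(
                f"{path} row {i}: unknown method {row.method!r}"
            )
        if code in out:
            raise InputValidationError(
                f"{path} row {i}: duplicate match-spec entry for {code}"
            )
        try:
            out[code] = MatchSpecEntry(
                food_code=code,
                method=method,
                target=_parse_target(method, row.target, path, i),
                note=getattr(row, "note", ""),
            )
        except InputValidationError as err:
            raise InputValidationError(f"{path} row {i}: {err}")
    return out


def write_match_spec(spec: Mapping[str, MatchSpecEntry], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "food_code": e.food_code,
                "method": e.method.value,
                "target": _serialize_target(e),
                "note": e.note,
            }
            for e in spec.values()
        ],
        columns=["food_code", "method", "target", "note"],
    ).to_csv(path, index=False)


def read_nutrient_profiles(path: PathLike) -> dict[str, dict[str, float]]:
    """Read long-format per-100 g nutrient profiles."""
    df = _read_csv(path, ["ingredient_id", "nutrient", "per_100g"])
    out: dict[str, dict[str, float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        out.setdefault(row.ingredient_id.strip(), {})[row.nutrient.strip()] = _float(
            row.per_100g, path, i, "per_100g"
        )
    return out


def read_intakes(path: PathLike) -> list[IntakeRecord]:
    df = _read_csv(path, ["food_code", "amount_g"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                IntakeRecord(
                    food_code=row.food_code.strip(),
                    amount_g=_float(row.amount_g, path, i, "amount_g"),
                    subject_id=getattr(row, "subject_id", ""),
                    day=int(getattr(row, "day", 1) or 1),
                )
            )
        except InputValidationError as err:
            raise InputValidationError(f"{path} row {i}: {err}")
    return records


def read_processing_pairs(path: PathLike) -> list[tuple[str, str, str]]:
    df = _read_csv(path, ["processed_item", "fresh_item", "category"])
    return [
        (r.processed_item.strip(), r.fresh_item.strip(), r.category.strip())
        for r in df.itertuples(index=False)
    ]


def _format_provenance(resolved: ResolvedGWP, decimals: int = 4) -> str:
    return "; ".join(
        f"{ident}:{round_half_up(contrib, decimals)}"
        for ident, contrib in resolved.provenance
    )


def write_database(
    resolved: Mapping[str, ResolvedGWP],
    foods: Mapping[str, FoodRecord],
    path: PathLike,
    config: Optional[BuildConfig] = None,
) -> None:
    """Export the built database, one row per input food.

    Values are rounded half-up to ``config.round_decimals`` (default 2);
    excluded foods are emitted with an empty value and stage ``excluded``.
    A food present in the details file but absent from ``resolved`` means
    the pipeline is incomplete and is an error.
    """
    config = config or BuildConfig()
    missing = sorted(set(foods) - set(resolved))
    if missing:
        raise InputValidationError(
            f"unresolved foods not marked excluded: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    rows = []
    for code in sorted(foods):
        r = resolved[code]
        rows.append(
            {
                "food_code": code,
                "name": foods[code].name,
                "gwp_star_kg_co2e_per_kg": (
                    ""
                    if r.excluded
                    else f"{round_half_up(r.value, config.round_decimals):.{config.round_decimals}f}"
                ),
                "stage": r.stage,
                "step": r.step,
                "coverage": "" if r.coverage is None else repr(float(r.coverage)),
                "provenance": _format_provenance(r),
                "note": r.note,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "food_code",
            "name",
            "gwp_star_kg_co2e_per_kg",
            "stage",
            "step",
            "coverage",
            "provenance",
            "note",
        ],
    ).to_csv(path, index=False)


def read_database(path: PathLike) -> pd.DataFrame:
    """Re-read an exported database; the value column becomes float
    (NaN for excluded foods), codes stay strings."""
    df = _read_csv(
        path, ["food_code", "gwp_star_kg_co2e_per_kg", "stage", "step"]
    )
    df["gwp_star_kg_co2e_per_kg"] = pd.to_numeric(
        df["gwp_star_kg_co2e_per_kg"].replace("", None)
    )
    if "coverage" in df.columns:
        df["coverage"] = pd.to_numeric(df["coverage"].replace("", None))
    return df
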