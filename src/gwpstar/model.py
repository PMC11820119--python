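"""Core domain types for GWP*-annotated food composition databases.

A *food composition database* holds one record per survey food, identified
by an 8-digit hierarchical code whose prefixes encode the classification
levels (major = first 2 digits, sub-major = first 3, minor = first 5).
A *GWP\\* reference table* maps item names to published climate-footprint
values in kg CO2e per kg of food; values may be negative (declining methane
emissions can make ruminant products net-cooling under GWP*).  A *match
specification* externalizes the expert judgment of how each food obtains
its value: copied from a reference item, computed from a weighted recipe,
approximated from its food group, or excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union


class GWPStarError(Exception):
    """Base class for all package errors."""


class InputValidationError(GWPStarError):
    """An input table violates its schema or invariants."""


class RecipeCycleError(GWPStarError):
    """The recipe / similar-food dependency relation contains a cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        path = " -> ".join(self.cycle + [self.cycle[0]]) if self.cycle else "?"
        super().__init__(f"dependency cycle detected: {path}")


class UnresolvableError(GWPStarError):
    """A food's assignment pathway cannot be completed."""


class Unapproximable(GWPStarError):
    """Signal: no stage-3 approximation is possible; the food is excluded."""


class MatchMethod(str, enum.Enum):
    """Assignment pathway for one food, as curated in the match spec."""

    DIRECT = "direct"
    APPROXIMATE = "approximate"
    RECIPE_FILE = "recipe_file"
    DESCRIPTION_RECIPE = "description_recipe"
    LABEL_RECIPE = "label_recipe"
    NUT_RECIPE = "nut_recipe"
    SIMILAR_FOOD = "similar_food"
    ONLINE_RECIPE = "online_recipe"
    GROUP_AVERAGE = "group_average"
    PROCESSING_FACTOR = "processing_factor"
    EXCLUDED = "excluded"


#: Fixed, total mapping from match method to (stage, step label).
#: Stage 1 = single-value matches, stage 2 = recipe calculations,
#: stage 3 = approximations; excluded foods carry no value.
STAGE_STEP: dict[MatchMethod, tuple[Union[int, str], str]] = {
    MatchMethod.DIRECT: (1, "direct"),
    MatchMethod.APPROXIMATE: (1, "approximate"),
    MatchMethod.RECIPE_FILE: (2, "recipe-file"),
    MatchMethod.DESCRIPTION_RECIPE: (2, "description"),
    MatchMethod.LABEL_RECIPE: (2, "label"),
    MatchMethod.NUT_RECIPE: (2, "nut-database"),
    MatchMethod.SIMILAR_FOOD: (2, "similar-food"),
    MatchMethod.ONLINE_RECIPE: (2, "online-recipe"),
    MatchMethod.GROUP_AVERAGE: (3, "group-average"),
    MatchMethod.PROCESSING_FACTOR: (3, "processing-factor"),
    MatchMethod.EXCLUDED: ("excluded", "excluded"),
}

#: Step labels in canonical (tabulation) order.
STEP_ORDER: tuple[str, ...] = tuple(step for _, step in STAGE_STEP.values())

#: Methods that produce inline ingredient lists (name-or-code, weight_g).
INLINE_RECIPE_METHODS = frozenset(
    {
        MatchMethod.DESCRIPTION_RECIPE,
        MatchMethod.LABEL_RECIPE,
        MatchMethod.NUT_RECIPE,
        MatchMethod.ONLINE_RECIPE,
    }
)


@dataclass(frozen=True)
class ClassificationScheme:
    """Prefix lengths of the hierarchical food-code classification."""

    code_length: int = 8
    major: int = 2
    sub_major: int = 3
    minor: int = 5

    def __post_init__(self):
        if not (0 < self.major < self.sub_major < self.minor <= self.code_length):
            raise InputValidationError(
                f"classification prefix lengths must be increasing and fit the "
                f"code length, got {self}"
            )

    def levels(self, code: str) -> tuple[str, str, str]:
        return code[: self.major], code[: self.sub_major], code[: self.minor]


DEFAULT_SCHEME = ClassificationScheme()


@dataclass(frozen=True)
class FoodRecord:
    """One database food with code-derived classification levels."""

    food_code: str
    name: str
    description: str = ""
    scheme: ClassificationScheme = DEFAULT_SCHEME

    def __post_init__(self):
        code = self.food_code
        if not code or not code.isdigit() or len(code) != self.scheme.code_length:
            raise InputValidationError(
                f"food_code {code!r} must be a {self.scheme.code_length}-digit string"
            )

    @property
    def major_code(self) -> str:
        return self.food_code[: self.scheme.major]

    @property
    def sub_major_code(self) -> str:
        return self.food_code[: self.scheme.sub_major]

    @property
    def minor_code(self) -> str:
        return self.food_code[: self.scheme.minor]


@dataclass(frozen=True)
class GWPReferenceEntry:
    """A published footprint value, kg CO2e per kg of food (may be negative)."""

    item_name: str
    gwp_value: float
    source_tag: str = ""

    def __post_init__(self):
        v = float(self.gwp_value)
        if v != v or v in (float("inf"), float("-inf")):
            raise InputValidationError(
                f"gwp_value for {self.item_name!r} must be finite, got {self.gwp_value!r}"
            )


@dataclass(frozen=True)
class RecipeRow:
    """One parent -> ingredient edge of the recipe table, weight in grams."""

    parent_food_code: str
    ingredient_food_code: str
    ingredient_weight_g: float

    def __post_init__(self):
        if self.ingredient_weight_g <= 0:
            raise InputValidationError(
                f"recipe weight must be > 0 for {self.parent_food_code} -> "
                f"{self.ingredient_food_code}, got {self.ingredient_weight_g}"
            )
        if self.parent_food_code == self.ingredient_food_code:
            raise InputValidationError(
                f"recipe self-loop on {self.parent_food_code}"
            )


#: An inline recipe ingredient: reference item name or food code, grams.
InlineIngredient = tuple[str, float]

#: Target of a processing-factor entry: (fresh reference item, category).
ProcessingTarget = tuple[str, str]

MatchTarget = Union[None, str, ProcessingTarget, list]


@dataclass(frozen=True)
class MatchSpecEntry:
    """The externalized human matching judgment for one food.

    ``target`` is method-dependent: a reference item name (direct /
    approximate), another food code (similar_food), an inline ingredient
    list (description / label / nut / online recipes), an optional group
    code (group_average), a (fresh item, category) pair
    (processing_factor), or None (recipe_file, excluded).
    """

    food_code: str
    method: MatchMethod
    target: MatchTarget = None
    note: str = ""

    def __post_init__(self):
        m = self.method
        t = self.target
        if m in (MatchMethod.DIRECT, MatchMethod.APPROXIMATE):
            if not isinstance(t, str) or not t:
                raise InputValidationError(
                    f"{self.food_code}: method {m.value} needs a reference item name"
                )
        elif m is MatchMethod.SIMILAR_FOOD:
            if not isinstance(t, str) or not t:
                raise InputValidationError(
                    f"{self.food_code}: similar_food needs a target food code"
                )
        elif m in INLINE_RECIPE_METHODS:
            if not isinstance(t, (list, tuple)) or not t:
                raise InputValidationError(
                    f"{self.food_code}: method {m.value} needs an inline ingredient list"
                )
            for item in t:
                if len(item) != 2 or float(item[1]) <= 0:
                    raise InputValidationError(
                        f"{self.food_code}: inline ingredient weights must be > 0"
                    )
        elif m is MatchMethod.PROCESSING_FACTOR:
            if not (isinstance(t, (list, tuple)) and len(t) == 2):
                raise InputValidationError(
                    f"{self.food_code}: processing_factor needs (fresh item, category)"
                )
            if t[1] not in ("fruit", "vegetable"):
                raise InputValidationError(
                    f"{self.food_code}: processing category must be fruit|vegetable, "
                    f"got {t[1]!r}"
                )

    @property
    def stage(self):
        return STAGE_STEP[self.method][0]

    @property
    def step(self) -> str:
        return STAGE_STEP[self.method][1]


@dataclass(frozen=True)
class ResolvedGWP:
    """A food's assigned value with stage/step provenance.

    ``coverage`` is the fraction of recipe weight carried by ingredients
    that could be valued; 1.0 for non-recipe pathways.  Excluded foods
    carry no value and no coverage.  ``provenance`` lists the immediate
    (identifier, contribution kg CO2e/kg) pairs behind the value.
    """

    food_code: str
    value: Optional[float]
    stage: Union[int, str]
    step: str
    coverage: Optional[float] = 1.0
    provenance: tuple = ()
    note: str = ""

    def __post_init__(self):
        if self.stage == "excluded":
            if self.value is not None:
                raise InputValidationError(
                    f"{self.food_code}: excluded foods carry no value"
                )
        elif self.value is None:
            raise InputValidationError(f"{self.food_code}: missing value")
        if self.coverage is not None and not (0.0 <= self.coverage <= 1.0 + 1e-12):
            raise InputValidationError(
                f"{self.food_code}: coverage {self.coverage} outside [0, 1]"
            )

    @property
    def excluded(self) -> bool:
        return self.stage == "excluded"


@dataclass(frozen=True)
class IntakeRecord:
    """One dietary intake record: food code and consumed amount in grams."""

    food_code: str
    amount_g: float
    subject_id: str = ""
    day: int = 1

    def __post_init__(self):
        if self.amount_g < 0:
            raise InputValidationError(
                f"negative intake amount {self.amount_g} for {self.food_code}"
            )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Operates on the shortest decimal repr of the float so that e.g. 0.185
    rounds to 0.19 rather than falling to the binary neighbour below.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent_half_up(count: int, total: int, decimals: int = 2) -> float:
    """Exact-decimal percentage 100*count/total, rounded half-up."""
    if total <= 0:
        raise InputValidationError("percentage of an empty total")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class BuildConfig:
    """Configuration knobs of the database build.

    excluded_ingredient_policy:
        ``renormalize`` removes unmatched ingredients from numerator and
        denominator of the recipe sum; ``zero`` keeps the denominator and
        treats unmatched ingredients as 0 kg CO2e/kg.
    sd_mode:
        ``sample`` (n-1 denominator) or ``population`` for group summaries.
    """

    excluded_ingredient_policy: str = "renormalize"
    sd_mode: str = "sample"
    round_decimals: int = 2
    nutrient_tolerance: float = 0.20
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)
    group_fallback: bool = True

    def __post_init__(self):
        if self.excluded_ingredient_policy not in ("renormalize", "zero"):
            raise InputValidationError(
                f"unknown excluded_ingredient_policy "
                f"{self.excluded_ingredient_policy!r}"
            )
        if self.sd_mode not in ("sample", "population"):
            raise InputValidationError(f"unknown sd_mode {self.sd_mode!r}")
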