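"""Stage-3 approximations: food-group averages and processing factors.

Foods that can be neither matched to a single reference value nor valued
from a recipe are approximated from their food group — the unweighted mean
over the *distinct* reference items that foods of the same classification
group were matched to — or, for processed produce, from the fresh
counterpart scaled by a processing conversion factor (the mean of
processed/fresh value ratios, computed separately for fruits and
vegetables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import (
    ClassificationScheme,
    DEFAULT_SCHEME,
    GWPReferenceEntry,
    InputValidationError,
    Unapproximable,
)

PROCESSING_CATEGORIES = ("fruit", "vegetable")


@dataclass(frozen=True)
class GroupAverage:
    """A group-average approximation with the items it drew on."""

    group_code: str
    level: str  # minor | sub_major | major
    items: tuple[str, ...]
    value: float


def group_average(
    minor_code: str,
    group_items: Mapping[str, Sequence[str]],
    reference: Mapping[str, GWPReferenceEntry],
    scheme: ClassificationScheme = DEFAULT_SCHEME,
    fallback: bool = True,
) -> GroupAverage:
    """Average the distinct reference items mapped to a food group.

    ``group_items`` maps classification prefixes (any level) to the
    reference items used by foods in that group; lookup starts at the
    minor level and, when ``fallback`` is on, widens to sub-major then
    major until a non-empty item set is found.  Raises
    :class:`Unapproximable` when every level is empty.
    """
    prefixes = [("minor", minor_code[: scheme.minor])]
    if fallback:
        prefixes += [
            ("sub_major", minor_code[: scheme.sub_major]),
            ("major", minor_code[: scheme.major]),
        ]
    for level, prefix in prefixes:
        items = sorted(set(group_items.get(prefix, ())))
        if items:
            missing = [i for i in items if i not in reference]
            if missing:
                raise InputValidationError(
                    f"group {prefix}: reference items not found: {missing}"
                )
            value = sum(reference[i].gwp_value for i in items) / len(items)
            return GroupAverage(prefix, level, tuple(items), value)
    raise Unapproximable(f"no reference items mapped to group {minor_code} at any level")


@dataclass(frozen=True)
class ProcessingFactor:
    """Mean processed/fresh value ratio for one produce category."""

    category: str
    pairs: tuple  # (processed id, fresh id, ratio)
    factor: float


def compute_processing_factor(
    pairs: Sequence[tuple], category: str
) -> ProcessingFactor:
    """Mean of processed/fresh ratios over ``(processed value, fresh value)``
    pairs (optionally ``(processed id, fresh id, processed value, fresh
    value)``).  Pairs with a zero fresh value are rejected with a warning;
    if none survive, an error is raised.
    """
    if category not in PROCESSING_CATEGORIES:
        raise InputValidationError(f"unknown processing category {category!r}")
    if not pairs:
        raise InputValidationError(f"no processed/fresh pairs for {category}")

    kept = []
    for pair in pairs:
        if len(pair) == 2:
            processed_id, fresh_id = "processed", "fresh"
            processed_v, fresh_v = pair
        else:
            processed_id, fresh_id, processed_v, fresh_v = pair
        if float(fresh_v) == 0.0:
            warnings.warn(
                f"{category} pair ({processed_id}, {fresh_id}) rejected: "
                f"fresh value is 0",
                stacklevel=2,
            )
            continue
        kept.append((processed_id, fresh_id, float(processed_v) / float(fresh_v)))
    if not kept:
        raise InputValidationError(
            f"all processed/fresh pairs for {category} had fresh value 0"
        )
    factor = sum(r for _, _, r in kept) / len(kept)
    return ProcessingFactor(category=category, pairs=tuple(kept), factor=factor)


def apply_processing_factor(fresh_value: float, factor: ProcessingFactor) -> float:
    """Approximate a processed food's value from its fresh counterpart."""
    return float(fresh_value) * factor.factor
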