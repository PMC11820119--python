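"""YAML/JSON build configuration loading."""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import BuildConfig, ClassificationScheme, InputValidationError

_KNOWN = {
    "excluded_ingredient_policy",
    "sd_mode",
    "round_decimals",
    "nutrient_tolerance",
    "group_fallback",
    "classification",
}


def load_config(path) -> BuildConfig:
    """Load a :class:`BuildConfig` from a YAML (or JSON) mapping.

    Recognized keys: ``excluded_ingredient_policy``, ``sd_mode``,
    ``round_decimals``, ``nutrient_tolerance``, ``group_fallback`` and a
    ``classification`` sub-mapping with ``code_length`` / ``major`` /
    ``sub_major`` / ``minor`` prefix lengths.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return BuildConfig()
    if not isinstance(raw, dict):
        raise InputValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN
    if unknown:
        raise InputValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k != "classification"}
    if "classification" in raw:
        kwargs["scheme"] = ClassificationScheme(**raw["classification"])
    return BuildConfig(**kwargs)
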