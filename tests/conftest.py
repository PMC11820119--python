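import pytest

from gwpstar import (
    BuildConfig,
    FoodRecord,
    GWPReferenceEntry,
    MatchMethod,
    MatchSpecEntry,
)


@pytest.fixture
def reference():
    """Tiny reference table with the worked single-value entries."""
    entries = [
        GWPReferenceEntry("Beef meat", 16.68),
        GWPReferenceEntry("Salt", 0.06),
        GWPReferenceEntry("Water", 0.0),
        GWPReferenceEntry("Tea leaves", 5.0),
        GWPReferenceEntry("Wheat flour", 0.4),
        GWPReferenceEntry("Lamb", -0.5),
    ]
    return {e.item_name: e for e in entries}


@pytest.fixture
def beef_foods():
    """Raw and cooked beef mince plus a similar-food chain."""
    foods = {
        "13101001": FoodRecord("13101001", "Beef, mince, <5% fat, raw"),
        "13101002": FoodRecord("13101002", "Beef, mince, <5% fat, cooked, no added fat"),
        "13101003": FoodRecord("13101003", "Beef, mince dish, takeaway style"),
    }
    spec = {
        "13101001": MatchSpecEntry("13101001", MatchMethod.DIRECT, "Beef meat"),
        "13101002": MatchSpecEntry("13101002", MatchMethod.APPROXIMATE, "Beef meat"),
        "13101003": MatchSpecEntry("13101003", MatchMethod.SIMILAR_FOOD, "13101001"),
    }
    return foods, spec


@pytest.fixture
def config():
    return BuildConfig()
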