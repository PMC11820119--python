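import math

import numpy as np
import pytest

from gwpstar import (
    BuildConfig,
    FoodRecord,
    GWPReferenceEntry,
    MatchMethod,
    MatchSpecEntry,
    RecipeCycleError,
    RecipeRow,
    ResolvedGWP,
    build_database,
    generate_bundle,
    summarize_by_group,
    write_database,
)


def test_synthetic_bundle_recovered_exactly():
    bundle, truth = generate_bundle(n_foods=200, seed=42)
    result = build_database(
        bundle.foods, bundle.recipes, bundle.reference, bundle.match_spec,
        processing_pairs=bundle.processing_pairs,
    )
    assert set(result.resolved) == set(bundle.foods)
    for code, expected in truth.values.items():
        got = result.resolved[code]
        if expected is None:
            assert got.excluded
        else:
            assert got.value == pytest.approx(expected, abs=1e-9)
            assert got.step == truth.steps[code]
            assert got.coverage == pytest.approx(truth.coverages[code], abs=1e-12)
    for step, n in truth.step_counts.items():
        assert result.tabulation.count(step) == n


def test_single_direct_food_bundle():
    bundle, truth = generate_bundle(n_foods=1, step_mix={"direct": 1.0}, seed=0)
    result = build_database(
        bundle.foods, bundle.recipes, bundle.reference, bundle.match_spec,
        processing_pairs=bundle.processing_pairs,
    )
    (code,) = bundle.foods
    assert result.resolved[code].value == pytest.approx(truth.values[code])
    assert result.tabulation.total == 1


def test_recipe_cycle_aborts_with_cycle_path():
    foods = {
        "11101001": FoodRecord("11101001", "A"),
        "11101002": FoodRecord("11101002", "B"),
    }
    spec = {
        c: MatchSpecEntry(c, MatchMethod.RECIPE_FILE, None) for c in foods
    }
    recipes = [
        RecipeRow("11101001", "11101002", 50.0),
        RecipeRow("11101002", "11101001", 50.0),
    ]
    reference = {"x": GWPReferenceEntry("x", 1.0)}
    with pytest.raises(RecipeCycleError) as err:
        build_database(foods, recipes, reference, spec)
    assert set(err.value.cycle) == {"11101001", "11101002"}


def test_missing_match_spec_entry_is_an_error():
    foods = {"11101001": FoodRecord("11101001", "A")}
    with pytest.raises(Exception, match="11101001"):
        build_database(foods, [], {"x": GWPReferenceEntry("x", 1.0)}, {})


def test_deterministic_byte_identical_export(tmp_path):
    bundle, _ = generate_bundle(n_foods=120, seed=9)
    paths = []
    for name in ("a.csv", "b.csv"):
        result = build_database(
            bundle.foods, bundle.recipes, bundle.reference, bundle.match_spec,
            processing_pairs=bundle.processing_pairs,
        )
        p = tmp_path / name
        write_database(result.resolved, bundle.foods, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def _resolved(code, value):
    if value is None:
        return ResolvedGWP(code, None, "excluded", "excluded", coverage=None)
    return ResolvedGWP(code, value, 1, "direct")


class TestGroupSummary:
    def test_known_sample_sd(self):
        foods = {
            f"1310100{i}": FoodRecord(f"1310100{i}", f"F{i}") for i in (1, 2, 3)
        }
        resolved = {
            c: _resolved(c, v) for c, v in zip(sorted(foods), (1.0, 2.0, 3.0))
        }
        out = summarize_by_group(resolved, foods).set_index("group_code")
        assert out.loc["13", "n"] == 3
        assert out.loc["13", "mean"] == pytest.approx(2.0)
        assert out.loc["13", "sd"] == pytest.approx(1.0)

    def test_single_food_group_has_empty_sd(self):
        foods = {"13101001": FoodRecord("13101001", "F")}
        out = summarize_by_group({"13101001": _resolved("13101001", 5.0)}, foods)
        assert out["n"].iloc[0] == 1
        assert math.isnan(out["sd"].iloc[0])

    def test_fully_excluded_group_reported_with_n_zero(self):
        foods = {
            "13101001": FoodRecord("13101001", "F"),
            "14101001": FoodRecord("14101001", "G"),
        }
        resolved = {
            "13101001": _resolved("13101001", 5.0),
            "14101001": _resolved("14101001", None),
        }
        out = summarize_by_group(resolved, foods).set_index("group_code")
        assert out.loc["14", "n"] == 0
        assert math.isnan(out.loc["14", "mean"])

    def test_planted_normal_draws_match_direct_computation(self):
        rng = np.random.default_rng(3)
        foods, resolved, per_group = {}, {}, {}
        for g, major in enumerate(("11", "12", "13")):
            vals = rng.normal(2.0, 0.5, size=10 + g)
            per_group[major] = vals
            for i, v in enumerate(vals):
                code = f"{major}101{i:03d}"
                foods[code] = FoodRecord(code, f"F{code}")
                resolved[code] = _resolved(code, float(v))
        out = summarize_by_group(resolved, foods).set_index("group_code")
        for major, vals in per_group.items():
            assert out.loc[major, "mean"] == pytest.approx(vals.mean(), abs=1e-12)
            assert out.loc[major, "sd"] == pytest.approx(
                vals.std(ddof=1), abs=1e-12
            )

    def test_population_sd_mode(self):
        foods = {
            f"1310100{i}": FoodRecord(f"1310100{i}", f"F{i}") for i in (1, 2)
        }
        resolved = {
            c: _resolved(c, v) for c, v in zip(sorted(foods), (1.0, 3.0))
        }
        out = summarize_by_group(resolved, foods, sd_mode="population")
        assert out["sd"].iloc[0] == pytest.approx(1.0)  # population SD of {1,3}


def test_coverage_below_one_foods_are_warned():
    bundle, truth = generate_bundle(
        n_foods=200, seed=2, unmatched_ingredient_rate=0.5
    )
    result = build_database(
        bundle.foods, bundle.recipes, bundle.reference, bundle.match_spec,
        processing_pairs=bundle.processing_pairs,
    )
    partial = [
        c for c, cov in truth.coverages.items() if cov is not None and cov < 1.0
    ]
    assert partial, "generator should plant partial-coverage recipes at this rate"
    warned = " ".join(result.report.warnings)
    for code in partial:
        assert code in warned


def test_zero_policy_keeps_unmatched_weight_in_denominator():
    # protein powder made up with water: powder excluded, water matched.
    # renormalize -> value of water alone (0); zero keeps the same here,
    # but with a non-zero matched ingredient the two policies separate.
    foods = {
        "11101001": FoodRecord("11101001", "Powder, prepared"),
        "11101002": FoodRecord("11101002", "Powder"),
    }
    spec = {
        "11101001": MatchSpecEntry("11101001", MatchMethod.RECIPE_FILE, None),
        "11101002": MatchSpecEntry("11101002", MatchMethod.EXCLUDED, None),
    }
    recipes = [
        RecipeRow("11101001", "11101002", 30.0),
        RecipeRow("11101001", "Milk", 170.0),
    ]
    reference = {"Milk": GWPReferenceEntry("Milk", 2.0)}
    args = (foods, recipes, reference, spec)
    renorm = build_database(*args).resolved["11101001"]
    zero = build_database(
        *args, config=BuildConfig(excluded_ingredient_policy="zero")
    ).resolved["11101001"]
    assert renorm.value == pytest.approx(2.0)
    assert zero.value == pytest.approx(2.0 * 170.0 / 200.0)
    assert renorm.coverage == zero.coverage == pytest.approx(0.85)


def test_build_report_text_lists_factors_and_exclusions():
    bundle, _ = generate_bundle(n_foods=100, seed=4)
    result = build_database(
        bundle.foods, bundle.recipes, bundle.reference, bundle.match_spec,
        processing_pairs=bundle.processing_pairs,
    )
    text = result.report.to_text()
    assert "Stage tabulation" in text
    assert "fruit" in text and "vegetable" in text
    for code, _ in result.report.excluded:
        assert code in text
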