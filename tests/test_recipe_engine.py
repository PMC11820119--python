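import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwpstar import (
    InputValidationError,
    RecipeCycleError,
    compute_composite_gwp,
    nutrient_consistency_report,
    recipe_from_description,
    validate_acyclic,
)


def resolver_from(values):
    return lambda ing: values.get(ing)


class TestCompositeValue:
    def test_symmetric_weighted_mean(self):
        res = compute_composite_gwp(
            "p", [("A", 50.0), ("B", 50.0)], resolver_from({"A": 2.0, "B": 4.0})
        )
        assert res.value == pytest.approx(3.0)
        assert res.coverage == 1.0

    def test_unmatched_ingredient_renormalizes(self):
        res = compute_composite_gwp(
            "p", [("A", 90.0), ("C", 10.0)], resolver_from({"A": 1.0})
        )
        assert res.value == pytest.approx(1.0)
        assert res.coverage == pytest.approx(0.9)
        assert res.excluded == (("C", 10.0),)

    def test_unmatched_ingredient_zero_policy_keeps_denominator(self):
        res = compute_composite_gwp(
            "p", [("A", 90.0), ("C", 10.0)], resolver_from({"A": 1.0}),
            policy="zero",
        )
        assert res.value == pytest.approx(0.9)
        assert res.coverage == pytest.approx(0.9)

    def test_all_unmatched_propagates_exclusion(self):
        res = compute_composite_gwp("p", [("C", 10.0)], resolver_from({}))
        assert res.unmatched
        assert res.value is None

    @pytest.mark.parametrize("rows", [[], [("A", 0.0)], [("A", -1.0)]])
    def test_degenerate_recipes_rejected(self, rows):
        with pytest.raises(InputValidationError):
            compute_composite_gwp("p", rows, resolver_from({"A": 1.0}))

    def test_nested_recipe_equals_flat_leaf_expansion(self):
        # 3 levels over 6 foods: leaves A,B,C; mid1 = A+B; mid2 = mid1+C;
        # top = mid2 + A.  Oracle: expand to leaf weights, apply the
        # weighted sum once.
        leaf = {"A": 1.5, "B": 4.0, "C": -0.5}
        mid1 = [("A", 30.0), ("B", 70.0)]
        mid2 = [("mid1", 50.0), ("C", 50.0)]
        top = [("mid2", 80.0), ("A", 20.0)]

        v_mid1 = compute_composite_gwp("mid1", mid1, resolver_from(leaf)).value
        v_mid2 = compute_composite_gwp(
            "mid2", mid2, resolver_from({**leaf, "mid1": v_mid1})
        ).value
        v_top = compute_composite_gwp(
            "top", top, resolver_from({**leaf, "mid2": v_mid2})
        ).value

        # flat: mid1 contributes 0.3/0.7 of its weight to A/B, etc.
        leaf_w = {"A": 0.0, "B": 0.0, "C": 0.0}
        leaf_w["A"] += 80.0 * 0.5 * 0.3 + 20.0
        leaf_w["B"] += 80.0 * 0.5 * 0.7
        leaf_w["C"] += 80.0 * 0.5
        total = sum(leaf_w.values())
        oracle = sum(w / total * leaf[k] for k, w in leaf_w.items())
        assert v_top == pytest.approx(oracle, abs=1e-9)


@settings(derandomize=True, max_examples=200)
@given(
    weights=st.lists(st.floats(0.1, 500.0), min_size=1, max_size=8),
    values=st.lists(st.floats(-20.0, 50.0), min_size=8, max_size=8),
    scale=st.floats(0.01, 100.0),
)
def test_convexity_and_homogeneity(weights, values, scale):
    rows = [(f"i{k}", w) for k, w in enumerate(weights)]
    table = {f"i{k}": values[k] for k in range(len(weights))}
    res = compute_composite_gwp("p", rows, resolver_from(table))
    used = [table[i] for i, _ in rows]
    assert min(used) - 1e-9 <= res.value <= max(used) + 1e-9
    scaled = compute_composite_gwp(
        "p", [(i, w * scale) for i, w in rows], resolver_from(table)
    )
    assert scaled.value == pytest.approx(res.value, rel=1e-9, abs=1e-9)


def test_monotonicity_in_one_ingredient_value():
    rows = [("A", 40.0), ("B", 60.0)]
    lo = compute_composite_gwp("p", rows, resolver_from({"A": 1.0, "B": 2.0}))
    hi = compute_composite_gwp("p", rows, resolver_from({"A": 1.5, "B": 2.0}))
    assert hi.value > lo.value


class TestDescriptionRecipes:
    def test_tea_leaves_per_litre_of_water(self):
        rows = recipe_from_description(
            [("Tea leaves", 15.0, "g"), ("Water", 1.0, "L")]
        )
        assert rows == [("Tea leaves", 15.0), ("Water", 1000.0)]
        gwp_tea = 5.0
        res = compute_composite_gwp(
            "tea", rows, resolver_from({"Tea leaves": gwp_tea, "Water": 0.0})
        )
        assert res.value == pytest.approx((15.0 / 1015.0) * gwp_tea)

    def test_single_ingredient_identity(self):
        rows = recipe_from_description([("Oats", 1.0, "fraction")])
        res = compute_composite_gwp("p", rows, resolver_from({"Oats": 0.7}))
        assert res.value == pytest.approx(0.7)

    def test_fractions_over_one_rejected(self):
        with pytest.raises(InputValidationError, match="sum"):
            recipe_from_description(
                [("A", 0.6, "fraction"), ("B", 0.5, "fraction")]
            )

    def test_mixed_units_rejected(self):
        with pytest.raises(InputValidationError):
            recipe_from_description([("A", 0.5, "fraction"), ("B", 10.0, "g")])

    def test_unknown_unit_rejected(self):
        with pytest.raises(InputValidationError, match="cup"):
            recipe_from_description([("A", 1.0, "cup")])


class TestCycleDetection:
    def test_cycle_raises_with_path(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("x", "a")]
        with pytest.raises(RecipeCycleError) as err:
            validate_acyclic(edges)
        assert set(err.value.cycle) == {"a", "b", "c"}

    def test_acyclic_graph_passes(self):
        validate_acyclic([("a", "b"), ("b", "c"), ("a", "c")])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    def test_injected_cycle_always_detected(self, n, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(n)]
        # forward (acyclic) edges plus one deliberate back edge
        edges = [
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.4
        ]
        i, j = sorted(rng.choice(n, size=2, replace=False))
        edges.append((nodes[i], nodes[j]))  # guarantee the forward path
        edges.append((nodes[j], nodes[i]))
        with pytest.raises(RecipeCycleError):
            validate_acyclic(edges)


class TestNutrientConsistency:
    def test_identity_recipe_zero_deviation(self):
        profile = {"protein_g": 10.0, "fat_g": 5.0}
        report = nutrient_consistency_report(
            [("A", 100.0)], {"A": profile}, profile
        )
        assert (report["rel_deviation"] == 0).all()
        assert not report["flagged"].any()

    def test_linear_mixing_matches_target(self):
        report = nutrient_consistency_report(
            [("A", 50.0), ("B", 50.0)],
            {"A": {"p": 10.0, "f": 0.0}, "B": {"p": 0.0, "f": 10.0}},
            {"p": 5.0, "f": 5.0},
        )
        assert (report["rel_deviation"] == 0).all()

    def test_three_ingredient_deviation_hand_computed(self):
        # composite protein = .2*20 + .3*10 + .5*2 = 8; target 10 -> dev .2
        # composite fat     = .2*5  + .3*15 + .5*1 = 6; target 4  -> dev .5
        report = nutrient_consistency_report(
            [("A", 20.0), ("B", 30.0), ("C", 50.0)],
            {
                "A": {"p": 20.0, "f": 5.0},
                "B": {"p": 10.0, "f": 15.0},
                "C": {"p": 2.0, "f": 1.0},
            },
            {"p": 10.0, "f": 4.0},
        ).set_index("nutrient")
        assert report.loc["p", "rel_deviation"] == pytest.approx(0.2)
        assert report.loc["f", "rel_deviation"] == pytest.approx(0.5)
        assert not report.loc["p", "flagged"]  # at the default 20% tolerance
        assert bool(report.loc["f", "flagged"])

    def test_missing_nutrient_reported_not_comparable(self):
        report = nutrient_consistency_report(
            [("A", 100.0)], {"A": {"p": 10.0}}, {"p": 10.0, "zinc": 1.0}
        ).set_index("nutrient")
        assert not report.loc["zinc", "comparable"]
        assert math.isnan(report.loc["zinc", "rel_deviation"])
        assert report.loc["p", "comparable"]
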