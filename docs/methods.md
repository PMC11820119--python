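# Methods

## Pipeline

The package builds a derived food composition database in which every
food either carries a GWP\* value (kg CO₂e per kg of food) with full
provenance, or is explicitly excluded. The build executes a curated
match-specification table — one entry per food naming its assignment
pathway and target — rather than attempting automated semantic matching:
matching national survey foods to climate reference items is expert
consensus work, and encoding it as data keeps the pipeline replicable
and auditable. The eleven pathways map onto a fixed stage/step scheme
(stage 1 direct/approximate, stage 2 the six recipe-based steps, stage 3
group-average and processing-factor, plus exclusion).

Resolution proceeds in dependency order over a food-level graph whose
edges run from each composite food to its ingredient foods and from each
similar-food entry to its target. The graph is validated acyclic up
front (networkx; the error reports one cycle path), then traversed in
lexicographic topological order, which makes the build deterministic and
independent of input row order. Reference items are always leaves.

## Recipe arithmetic

A composite food's value is the weight-proportional sum of ingredient
values. Two decisions here were genuinely open:

* **Unmatched ingredients.** The default `renormalize` policy removes an
  unvalued ingredient *and its weight* from the calculation, i.e. the
  value is the weighted mean over the matched weight only. The
  alternative reading — keep the total weight in the denominator,
  effectively valuing unmatched ingredients at 0 — is available as
  `excluded_ingredient_policy: zero`. Both policies report the same
  *coverage* (matched weight / total weight), and a recipe in which
  nothing can be valued propagates exclusion upward under either policy.
* **Coverage does not inherit.** Once a composite ingredient is
  resolved, its parent treats it as fully specified: the parent's
  coverage reflects only its own unmatched ingredients. The alternative
  (multiplying child coverages up the tree) would conflate "how much of
  this recipe is valued" with "how much of the entire expansion is
  valued"; the per-food coverage field answers the first question, and
  the build report's warnings list every coverage < 1 food so the second
  can be audited.

Description-derived recipes convert stated amounts to grams with
water-like liquids at 1 g/mL; proportion-style descriptions must sum to
at most 1 (tolerance 1e-6) and are scaled to a 100 g basis. No cooking
yield or moisture-change factors are applied — recipe weights are used
as given.

The nutrient-consistency report replaces an interactive dietary-software
check: the composite's per-100 g nutrient profile (weight-proportional
mix of ingredient profiles) is compared with the target food's profile,
with relative deviations flagged above a configurable tolerance (default
20%) and missing nutrients reported as not comparable rather than
failing the build.

## Approximations

Group averages take the **unweighted mean over distinct reference
items** mapped to the group — items, not database foods, so a group with
forty foods matched to five items averages five values. The mapping is
derived from the stage-1 assignments in each classification prefix;
lookup starts at the minor (5-digit) group and falls back to sub-major
then major (configurable off), logging every fallback. A group empty at
all levels makes the food excluded.

Processing factors are the **mean of processed/fresh value ratios**
(not the ratio of summed means), computed separately for fruits and
vegetables from an input table of counterpart item pairs; pairs with a
zero fresh value are dropped with a warning. The discriminating fixture
{(2,1),(9,3)} → 2.5 (not 11/4) locks the choice in the test suite.

## Rounding and export

Internal computation keeps full float precision; rounding to two
decimals happens only at export, half-up on the shortest decimal
representation (so 0.185 → 0.19 and 16.684999 → 16.68). Rounding
intermediates would compound error through nested recipes. Tabulation
percentages use exact decimal division before the same half-up
quantization. Half-up was chosen over banker's rounding as the
convention of printed nutrient tables; it is the single place the two
rules differ visibly.

Group summaries default to the sample SD (n − 1), the descriptive
convention for food-group statistics, with `sd_mode: population`
available; a single-food group reports an empty SD, and a fully excluded
group appears with n = 0 rather than vanishing.

## Synthetic data: what it emulates, and what it does not

The generator plants a pathway mix (default: the step proportions
observed in national mapping exercises — about 35% stage 1, 55% stage 2,
6% stage 3, 4% excluded), hierarchical 8-digit codes across ≥ 5 major
groups, a 232-item reference table with log-normal values
(median ≈ 0.8 kg CO₂e/kg, heavy right tail reaching the tens, 2%
negated to emulate net-cooling ruminant products, plus Water = 0 and
Salt = 0.06), acyclic recipes nested to a configurable depth (default 3,
2–6 ingredients of 5–300 g), a 15% chance per recipe of one unmatchable
ingredient (planting coverage < 1), and three processed/fresh counterpart
pairs per produce category. Intake amounts are gamma(2, 75) grams
(mean 150 g per record, right-skewed like real serving sizes), with 10%
of records hitting excluded foods.

Ground truth is computed by a deliberately separate, non-recursive
bottom-up leaf-composition expansion, so a bug in the pipeline's
recursive resolution cannot cancel in both code paths. Ground truth
assumes the default configuration (renormalize policy, fallback on).

What passing these tests shows: the arithmetic, the exclusion and
renormalization rules, provenance accounting, and the reporting
arithmetic are correct on inputs with the real data's *structure*. What
it does not show: anything about the semantic quality of a real match
specification, the representativeness of real reference values, or real
recipe weights — the generator's names and values are synthetic, and the
per-group statistics of a synthetic bundle have no nutritional meaning.

## Numerical choices and degenerate inputs

Equality tolerances in the oracle tests are absolute 1e-9 (values are
O(10), weights O(100); double precision leaves ~1e-13 headroom).
Zero-weight or negative-weight recipe rows, empty recipes, zero total
weight, duplicate food codes or reference names, malformed codes, and
fraction sums > 1 are hard validation errors naming the offending row.
Duplicate ingredient rows within one recipe are legal and simply sum.
A similar-food chain ending in an excluded food is itself excluded; a
cycle anywhere aborts the build with the cycle path.

Problem sizes in the shipped test and acceptance runs — 500 random
recipe DAGs, 20 bundles of 200 foods plus 2 of 2000, 10 × 20 intake
records — were chosen as the smallest sizes that exercise every pathway
and nesting level several times over; all complete in seconds.

## Known limitations

* The pipeline consumes a match specification; it cannot author one.
* Packaging, storage and preparation emissions are outside the metric's
  scope, and excluded-ingredient renormalization biases composite values
  toward their matched ingredients — both underestimate true footprints,
  which the coverage field and the footprint report's excluded-intake
  note surface but do not correct.
* Classification prefixes are positional; classification schemes that
  are not prefix codes would need a different `ClassificationScheme`.
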