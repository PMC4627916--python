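# Methods

## The problem

Packaged-food labels in the EU reveal two things about a product's
recipe: the ingredient list, ordered by descending amount but without
quantities, and a declared panel per 100 g (energy, carbohydrate, sugar,
protein, fat, saturated fat, fiber — rounded). Given a reference
food-composition table for the ingredients, those constraints are often
enough to back-calculate the recipe approximately and hence to
*extrapolate* nutrients the label does not declare (minerals, vitamins,
fatty-acid classes). This package formalises that back-calculation, the
database built from it, and the downstream matched GF-vs-GC comparison,
classification and cost analyses.

## Recipe model and deconvolution

A product is a mixture of its k listed ingredients at unknown
percentages p with

- ordering: p₁ ≥ p₂ ≥ … ≥ p_k ≥ 0 (descending-order labelling;
  non-strict, since equal-quantity ingredients are listed arbitrarily),
- mass balance: Σp ≤ 100, with the residual 100 − Σp treated as
  water/moisture added in processing, credited to the water column only.

Every nutrient is linear in p: theoreticalₙ(p) = Σᵢ (pᵢ/100) ·
compositionₙ(ingredientᵢ). A nutrient is *missing* in the output iff it
is missing in any contributing ingredient — missing is never coerced
to 0, and missing values later drop out of group means with reduced n.

The estimator minimises the weighted squared *relative* deviation over
the declared nutrients with positive label values; relative deviations
put all nutrients on the dimensionless scale that the survey's
"estimation precision" (100 × theoretical/label, %) is defined on.
Energy is computed from the macronutrient panel with Atwater-type
factors and carries weight 2 (the manual iteration this formalises
stopped on label energy); all other weights are 1.

**Energy factors.** 4 kcal/g for carbohydrate and protein, 9 for fat,
2 for fiber (EU convention); the fiber factor can be set to 0. The
survey never states its convention; its printed panels are consistent
with either choice to within ~5–7 %, so energy checks against printed
values are tolerance-based.

**Solver.** Reparametrising to difference coordinates pᵢ = Σ_{j≥i} d_j
turns the ordering constraint into d ≥ 0 and the mass balance into one
linear inequality; the objective is a convex quadratic. When the
nonnegativity-only optimum (Lawson–Hanson NNLS) respects Σp ≤ 100 — the
usual case, since recipes carry a water residual — it is returned
exactly. Otherwise the optimum lies on Σp = 100 and is found by
`trust-constr` followed by an equality-constrained active-set polish.
Convergence is declared when the KKT residual (distance of the gradient
from the cone of active-constraint normals, computed by NNLS) falls
below 1e-8 relative to the gradient scale; 500 iterations maximum. Both
are configurable (`EstimateOptions`).

**Uniqueness.** Labels under-determine recipes whenever ingredient
signatures are collinear over the declared panel (two sugars are
indistinguishable). The estimator reports this: the dimension of the
optimal face is the nullity of the fit matrix restricted to directions
not pinned by *strongly* active constraints (positive multiplier —
weakly active bounds at a vertex of a flat face do not pin it). Any
positive face dimension flags the estimate `under-determined`. The
theoretical composition — and therefore the database row — is still
well-defined up to that face for the fitted nutrients; extrapolated
micronutrients inherit the ambiguity, which is the honest limit of
label-based estimation.

**Infeasible labels** (e.g. a declared energy no mixture can reach)
produce a diagnostic result with a large objective value and
`converged` judged by the same KKT rule — never an exception.

**Grid oracle.** `brute_force_recipe` enumerates the ordered simplex on
a percent grid (guarded to k ≤ 4, step ≥ 0.1 %) under the same
objective, as an independent check of the continuous solver; tests
assert two-sided objective equivalence up to grid resolution.

## Synthetic world

The generator stands in for the proprietary reference databases and the
physical supermarket survey. What it emulates, and what it does not:

- **Ingredients** come from seven archetype families (starch/flour,
  sugar, fat/oil, protein source, vegetable, dairy, additive) with
  per-100 g nutrient ranges typical of each family; energies are derived
  from macros with the default factors, so label energy and theoretical
  energy are mutually consistent. Water fills most of the non-solid
  remainder. Micronutrients are small random amounts (salt-like
  additives are the only sodium-rich family).
- **Recipes**: ingredient identities drawn uniformly without
  replacement; proportions from a symmetric Dirichlet(1) sorted
  descending — the simplest exchangeable prior consistent with
  descending-order labels — scaled to 100 minus a uniform 0–15 % water
  residual. The residual makes the under-determination real labels
  exhibit explicit and testable.
- **Labels** declare the proportion-weighted panel, optionally perturbed
  by relative Gaussian noise (default SD 0: EU labels are compiled from
  supplier specifications, not independent assays), then rounded to EU
  label precision: whole kcal; macros to 0.1 g, with values below 0.5 g
  declared as 0 (the EU guidance rule — printing "0.1 g" would carry
  rounding error as large as the value and would poison a relative-error
  fit with sub-precision targets).
- **Catalog**: per GF product, two same-category GC counterparts with
  cost-per-kg multipliers U(0.8, 1.0) (budget) and U(1.0, 1.4) (premium)
  on a per-category base cost, and a GF multiplier U(2.0, 2.7) —
  mirroring the surveyed 205–267 % cost ratios. Category base costs
  (1.5–9 €/kg) bracket a conventional supermarket basket averaging
  ~6.6 €/kg. Optional planted duplicates/incompletes exercise the
  exclusion filter, and a configurable GF protein shift plants a known
  group effect for power studies.

Not emulated: brand identity, fortification, cooking losses, price time
series, or correlated ingredient co-occurrence. A green synthetic test
therefore establishes that the *machinery* recovers what labels encode —
not that any particular real-world nutrient estimate is accurate, which
also depends on reference-table fidelity.

What the defaults imply for accuracy: with zero declared-value noise and
default rounding, every macronutrient estimation precision across 200
seeded products (3–8 ingredients) stays within 100 ± 7 % — the envelope
the original manual procedure reported — with typical worst cases of
4–6 %, driven by rounding on small declared values. On rounding-free
labels with linearly independent ingredient signatures, recovery is
exact to well under 0.5 percentage points.

## Survey fixtures and weighting

The packaged tables transcribe the published GF product tables: 58 rows
(macros and micros separately, joined on product id), of which 5 are
pooled means of two very similar products and carry `pooled_weight` 2 —
63 products by weight. Pooled rows count double in every weighted
summary; this is the only weighting under which the published category
means (bread/bakery energy 270.5 kcal, flour/bake-mix protein 4.6 g,
overall protein 5.8 g, …) are recovered exactly from the printed rows.

Two SD conventions coexist in the source report: prose uses the sample
SD (n−1), its comparison table the population SD (n); both reproduce
from the same cereal sodium triple (491.3 ± 91.6 vs ± 74.8). The package
computes and labels both, reporting sample SD by default. For categories
containing pooled rows, SDs computed from (possibly pooled) rows can
understate the SD of the unpooled underlying data, which the source did
not print; means are unaffected.

## Classification and known non-reproducible claims

Claim thresholds are strict as printed: low sodium < 120 mg/100 g, high
sodium > 500, high fiber > 6 g/100 g. Strictness matters: the
high-fiber share of the GF fixtures is 19 % only because a row sitting
exactly at 6.0 g is excluded. Prevalences are pooled-weight shares of
*determinable* products (missing deciding nutrient → excluded from
numerator and denominator).

Implemented as stated but flagged rather than matched: the published
"65 % low sodium" claim recomputes to ~35 % from the published GF tables
under the printed rule (every weighting tried), and "27 % high sodium"
refers to GF and GC products jointly while the GC profiles were never
published. The classification report carries these flags verbatim.

## Statistics

- Group comparisons: two-sided unpaired t-tests, pooled-variance Student
  by default (matching F = t² reporting of two-group one-way ANOVA);
  Welch is an explicit option. Integer pooled weights enter as exact
  replication.
- Bonferroni family: the seven per-category tests of one nutrient
  (m = 7); the overall test per nutrient stands alone. The source does
  not define its family; this is the package's choice.
- χ²: Pearson on 2×2 tables without continuity correction, df = 1.
- Post-hoc power for two independent means: noncentral t with
  δ = d·√(n₁n₂/(n₁+n₂)), pooled Cohen's d, two-sided α = 0.05 default.
  Verified against a 200 000-replicate simulation and against
  statsmodels' independent implementation. The survey's printed 95.7 %
  power value is not reproducible from any printed (mean, SD, n)
  combination and is not asserted anywhere.

## Cost analysis

Costs are price × 1000 / package mass (€/kg). The disparity per
category is relative_pct = 100 × mean_GF / mean_GC over the matched
sets, with the GC mean taken over both counterparts. Because published
"+205 %…+267 %" phrasing is ambiguous between a ratio (GF = 2.05–2.67 ×
GC) and an excess (GF − GC), both `relative_pct` and `excess_pct` are
always emitted. Note the generator's tier multipliers average 1.05 for
GC, so a pinned GF multiplier m is recovered as 100·m/1.05, not 100·m.

## Degenerate inputs and tie-breaks

- Counterpart matching breaks €/kg ties by ascending product name,
  making the match invariant to pool ordering.
- Duplicate detection normalises whitespace/case on names and compares
  declared panels exactly; duplicates are removed before incompleteness
  is assessed, keeping first occurrences.
- Zero-variance equal-mean group pairs give t = 0, p = 1; single-value
  groups have undefined SDs (reported as such, never 0).
- A label whose declared sugar exceeds carbohydrate is rejected, with a
  0.1 g slack for independently rounded values; the fatty-acid split
  check (SFA+MUFA+PUFA ≤ 1.05 × fat) is a warning only, because
  published tables themselves violate it on individual rows.

## Limitations

- Extrapolated micronutrients are only as identifiable as the declared
  panel allows; under-determined recipes are flagged, not resolved.
- Raw-form per-100 g arithmetic ignores cooking losses and retention
  factors.
- The packaged fixtures carry no price data, so the published overall GF
  mean cost (11.58 €/kg) cannot be recomputed here; cost analyses are
  exercised on synthetic catalogs only.
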