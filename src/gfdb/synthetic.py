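"""Synthetic reference tables, recipes, labels and matched catalogs.

The proprietary reference databases (BLS / OeNWT) and the physical
supermarket survey cannot be redistributed, so every downstream stage is
exercised against a generated world with the same statistical structure:

* ingredients drawn from seven archetype families (starch/flour, sugar,
  fat/oil, protein source, vegetable, dairy, additive) with nutrient
  ranges typical of each family;
* recipes with symmetric-Dirichlet proportions sorted descending (the
  simplest exchangeable prior consistent with descending-order ingredient
  lists) plus a uniform 0-15 % water/moisture residual, which makes the
  under-determination real labels exhibit explicit;
* labels that declare the proportion-weighted panel, optionally perturbed
  by relative Gaussian noise and then rounded to EU label precision
  (whole kcal, 0.1 g macros) — quantities are never emitted, only order;
* matched 1 GF : 2 GC sets with per-category base costs and cost-tier
  multipliers (budget U(0.8,1.0), premium U(1.0,1.4)) and a GF cost
  multiplier U(2.0, 2.7), mirroring the surveyed +105..167 % excess /
  205-267 % ratio range.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import CATEGORIES, CompositionTable, FoodLabel, IngredientRecord
from .deconvolution import EnergyFactors, energy_from_macros, theoretical_composition
from .nutrients import InvariantError, NutrientVector

FAMILIES: tuple[str, ...] = (
    "starch",
    "sugar",
    "fat",
    "protein",
    "vegetable",
    "dairy",
    "additive",
)

#: Default gluten-containing base cost per category, EUR/kg. Chosen to
#: bracket a supermarket basket averaging ~6.6 EUR/kg across categories.
DEFAULT_BASE_COST: Mapping[str, float] = {
    "flour/bake mix": 1.5,
    "bread/bakery": 4.0,
    "pasta/cereal-based": 2.5,
    "cereals": 5.0,
    "cookies/cakes": 8.0,
    "snacks": 9.0,
    "convenience": 8.5,
}


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator; defaults mirror the surveyed design."""

    n_ingredients: int = 63
    n_gf_products: int = 63
    ingredients_per_product: tuple[int, int] = (3, 8)
    water_residual_range: tuple[float, float] = (0.0, 15.0)
    noise_sd_rel: float = 0.0  # relative SD of declared-value noise
    label_rounding: bool = True  # whole kcal, 0.1 g macros
    gf_cost_multiplier: tuple[float, float] = (2.0, 2.7)
    budget_multiplier: tuple[float, float] = (0.8, 1.0)
    premium_multiplier: tuple[float, float] = (1.0, 1.4)
    base_cost_eur_per_kg: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_COST)
    )
    planted_protein_shift_g: float = 0.0  # added to GF declared protein
    n_planted_duplicates: int = 0
    n_planted_incomplete: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ingredients < 1 or self.n_gf_products < 1:
            raise InvariantError("counts must be >= 1")
        lo, hi = self.ingredients_per_product
        if not 1 <= lo <= hi:
            raise InvariantError("invalid ingredients_per_product range")
        if self.noise_sd_rel < 0:
            raise InvariantError("noise SD must be >= 0")
        if min(self.gf_cost_multiplier) < 1:
            raise InvariantError("GF cost multiplier range must be >= 1")


@dataclass(frozen=True)
class RecipeTruth:
    """Ground-truth proportions behind one synthetic label."""

    product_id: str
    proportions: tuple[tuple[str, float], ...]
    water_residual_pct: float
    seed: int

    def __post_init__(self) -> None:
        pcts = [p for _, p in self.proportions]
        if any(p <= 0 for p in pcts):
            raise InvariantError("truth proportions must be > 0")
        if any(pcts[i] < pcts[i + 1] for i in range(len(pcts) - 1)):
            raise InvariantError("truth proportions must be non-increasing")
        if abs(sum(pcts) + self.water_residual_pct - 100.0) > 1e-9:
            raise InvariantError("proportions + water residual must equal 100")


def _family_vector(family: str, rng: np.random.Generator) -> dict[str, float]:
    """Draw one ingredient composition (per 100 g) for an archetype family."""
    u = rng.uniform
    if family == "starch":
        carb = u(70, 88)
        sugar = min(carb, u(0, 3))
        protein, fat, fiber = u(0.3, 8), u(0.5, 3), u(1, 8)
    elif family == "sugar":
        carb = u(95, 100)
        sugar = carb  # by definition of the family
        protein, fat, fiber = 0.0, 0.0, 0.0
    elif family == "fat":
        carb = u(0, 1)
        sugar = min(carb, u(0, 0.5))
        protein, fat, fiber = u(0, 1), u(80, 100), 0.0
    elif family == "protein":
        carb = u(5, 30)
        sugar = min(carb, u(0, 5))
        protein, fat, fiber = u(20, 80), u(1, 15), u(0, 6)
    elif family == "vegetable":
        carb = u(3, 10)
        sugar = carb * u(0.2, 0.6)
        protein, fat, fiber = u(1, 3), u(0, 1), u(1, 4)
    elif family == "dairy":
        carb = u(3.5, 5)
        sugar = carb * u(0.8, 1.0)
        protein, fat, fiber = u(3, 4), u(1, 4), 0.0
    elif family == "additive":
        carb = u(0, 60)
        sugar = min(carb, u(0, 2))
        protein, fat, fiber = 0.0, 0.0, u(0, 50)
    else:  # pragma: no cover
        raise ValueError(family)
    sfa_frac = u(0.1, 0.7)
    mufa_frac = u(0.1, 0.9 - sfa_frac)
    amounts: dict[str, float] = {
        "carbohydrate_g": carb,
        "sugar_g": sugar,
        "protein_g": protein,
        "fat_g": fat,
        "sfa_g": fat * sfa_frac,
        "mufa_g": fat * mufa_frac,
        "pufa_g": fat * max(0.0, 0.95 - sfa_frac - mufa_frac),
        "fiber_g": fiber,
    }
    solids = carb + protein + fat + fiber
    amounts["water_g"] = max(0.0, 100.0 - solids) * u(0.6, 1.0)
    # Micronutrients: small log-uniform amounts; salt-like additives are
    # the only sodium-rich family.
    sodium_hi = 25000.0 if family == "additive" else 600.0
    amounts["sodium_mg"] = float(np.exp(u(np.log(0.5), np.log(sodium_hi))))
    for name, hi in (
        ("potassium_mg", 400.0),
        ("calcium_mg", 150.0),
        ("phosphorus_mg", 300.0),
        ("iron_mg", 4.0),
        ("zinc_mg", 3.0),
        ("cholesterol_mg", 50.0 if family in ("dairy", "protein") else 1.0),
        ("vitE_mg", 3.0),
        ("vitC_mg", 5.0),
        ("thiamin_mg", 0.4),
        ("riboflavin_mg", 0.3),
        ("niacin_mg", 3.0),
        ("vitD_ug", 0.2),
        ("retinol_ug", 10.0),
        ("bcarotene_ug", 100.0),
    ):
        amounts[name] = u(0.0, hi)
    macros = NutrientVector.from_mapping(
        {k: amounts[k] for k in ("carbohydrate_g", "protein_g", "fat_g", "fiber_g")}
    )
    amounts["energy_kcal"] = energy_from_macros(macros, EnergyFactors())
    return amounts


def generate_ingredient_table(config: SynthConfig) -> CompositionTable:
    """Deterministic archetype-family reference table of ``n_ingredients``."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_ingredients):
        family = FAMILIES[i % len(FAMILIES)]
        amounts = _family_vector(family, rng)
        records.append(
            IngredientRecord(
                ingredient_id=f"ing{i:04d}",
                name=f"{family} #{i}",
                composition=NutrientVector.from_mapping(amounts),
            )
        )
    return CompositionTable(records)


def ingredient_family(ingredient_id: str) -> str:
    """Archetype family an id generated here belongs to."""
    return FAMILIES[int(ingredient_id.removeprefix("ing")) % len(FAMILIES)]


def generate_recipe(
    k: int,
    table: CompositionTable,
    seed: int,
    *,
    product_id: str = "synth",
    water_residual_range: tuple[float, float] = (0.0, 15.0),
) -> RecipeTruth:
    """Sorted symmetric-Dirichlet recipe over ``k`` distinct ingredients."""
    if not 1 <= k <= len(table):
        raise InvariantError(f"need 1 <= k <= {len(table)}, got {k}")
    rng = np.random.default_rng(seed)
    ids = list(rng.choice(table.ids, size=k, replace=False))
    residual = float(rng.uniform(*water_residual_range))
    shares = np.sort(rng.dirichlet(np.ones(k)))[::-1]
    # Degenerate zero shares would break the strict-positivity invariant.
    shares = np.maximum(shares, 1e-6)
    shares /= shares.sum()
    pcts = shares * (100.0 - residual)
    return RecipeTruth(
        product_id=product_id,
        proportions=tuple((i, float(p)) for i, p in zip(ids, pcts)),
        water_residual_pct=residual,
        seed=seed,
    )


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10.0**decimals
    return float(np.floor(x * scale + 0.5) / scale)


def _round_label_value(name: str, value: float) -> float:
    """EU label rounding: whole kcal; macros to 0.1 g, below 0.5 g as 0.

    The sub-0.5 g rule matters: a declared "0.1 g" would carry a rounding
    error as large as the value itself, and EU labelling guidance instead
    prints 0 for such amounts.
    """
    if name == "energy_kcal":
        return _round_half_up(value, 0)
    if value < 0.5:
        return 0.0
    return _round_half_up(value, 1)


def render_label(
    truth: RecipeTruth,
    table: CompositionTable,
    config: SynthConfig,
    *,
    category: str = "flour/bake mix",
    gluten_free: bool = True,
    price_eur: float = 2.0,
    package_mass_g: float = 500.0,
    rng: np.random.Generator | None = None,
) -> FoodLabel:
    """Render the label a manufacturer would print for a known recipe.

    The declared panel is the theoretical composition of the true recipe,
    optionally perturbed by relative Gaussian noise, then rounded to label
    precision. Ingredient order (not quantity) is all the label reveals.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    theo = theoretical_composition(
        truth.proportions, table, water_residual_pct=truth.water_residual_pct
    )
    panel: dict[str, float] = {}
    for name in (
        "energy_kcal",
        "carbohydrate_g",
        "sugar_g",
        "protein_g",
        "fat_g",
        "sfa_g",
        "fiber_g",
    ):
        value = theo.get(name)
        if value is None:
            continue
        if config.noise_sd_rel > 0:
            value *= 1.0 + config.noise_sd_rel * float(rng.standard_normal())
        panel[name] = max(0.0, value)
    if gluten_free and config.planted_protein_shift_g:
        panel["protein_g"] = max(
            0.0, panel.get("protein_g", 0.0) + config.planted_protein_shift_g
        )
    if config.label_rounding:
        for name, value in panel.items():
            panel[name] = _round_label_value(name, value)
    if "sugar_g" in panel and "carbohydrate_g" in panel:
        panel["sugar_g"] = min(panel["sugar_g"], panel["carbohydrate_g"])
    return FoodLabel(
        product_id=truth.product_id,
        name=f"product {truth.product_id}",
        category=category,
        gluten_free=gluten_free,
        ingredients_desc=tuple(i for i, _ in truth.proportions),
        declared=NutrientVector.from_mapping(panel),
        price_eur=price_eur,
        package_mass_g=package_mass_g,
    )


def generate_catalog(
    config: SynthConfig, table: CompositionTable | None = None
) -> tuple[list[FoodLabel], list[RecipeTruth]]:
    """Matched survey catalog: per GF product, two same-category GC labels.

    Returns all labels (GF first within each matched triple) and the
    recipe truths for every product, GF and GC alike. Optional planted
    duplicates and incomplete labels are appended at the end for the
    exclusion-filter tests.
    """
    table = table if table is not None else generate_ingredient_table(config)
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.ingredients_per_product
    labels: list[FoodLabel] = []
    truths: list[RecipeTruth] = []
    masses = np.array([250.0, 500.0, 750.0, 1000.0])

    for i in range(config.n_gf_products):
        category = CATEGORIES[i % len(CATEGORIES)]
        base = config.base_cost_eur_per_kg[category]
        for role, suffix, gf in (("gf", "", True), ("budget", "b", False), ("premium", "p", False)):
            pid = f"p{i:03d}{suffix}"
            k = int(rng.integers(lo, hi + 1))
            recipe_seed = int(rng.integers(0, 2**31 - 1))
            truth = generate_recipe(
                k,
                table,
                recipe_seed,
                product_id=pid,
                water_residual_range=config.water_residual_range,
            )
            if role == "gf":
                mult = rng.uniform(*config.gf_cost_multiplier)
            elif role == "budget":
                mult = rng.uniform(*config.budget_multiplier)
            else:
                mult = rng.uniform(*config.premium_multiplier)
            mass = float(rng.choice(masses))
            cost_kg = base * float(mult)
            labels.append(
                render_label(
                    truth,
                    table,
                    config,
                    category=category,
                    gluten_free=gf,
                    price_eur=cost_kg * mass / 1000.0,
                    package_mass_g=mass,
                    rng=rng,
                )
            )
            truths.append(truth)

    gf_labels = [lb for lb in labels if lb.gluten_free]
    for j in range(config.n_planted_duplicates):
        src = gf_labels[j % len(gf_labels)]
        labels.append(replace(src, product_id=f"dup{j:03d}"))
    for j in range(config.n_planted_incomplete):
        src = gf_labels[j % len(gf_labels)]
        labels.append(
            replace(
                src,
                product_id=f"inc{j:03d}",
                name=f"{src.name} (incomplete {j})",
                declared=src.declared.replace(protein_g=None),
            )
        )
    return labels, truths


def matched_sets_from_catalog(labels: Sequence[FoodLabel]) -> list["MatchedSet"]:
    """Rebuild the generator's 1 GF : 2 GC triples as matched sets.

    Each GF product is paired with its *own* generated counterparts (ids
    ``<gf>b`` and ``<gf>p``), assigning budget/premium by cost per kg —
    the survey's deliberate per-product matching, as opposed to
    re-matching against the whole category pool.
    """
    from .core import MatchedSet

    by_id = {lb.product_id: lb for lb in labels}
    sets = []
    for lb in labels:
        if not lb.gluten_free or lb.product_id not in by_id:
            continue
        a = by_id.get(lb.product_id + "b")
        b = by_id.get(lb.product_id + "p")
        if a is None or b is None:
            continue
        budget, premium = sorted(
            (a, b), key=lambda x: (x.cost_eur_per_kg, x.name)
        )
        sets.append(
            MatchedSet(gf=lb, budget_counterpart=budget, premium_counterpart=premium)
        )
    return sets
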