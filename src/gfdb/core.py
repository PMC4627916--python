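"""Domain types for the packaged-food survey: reference ingredients,
food labels, catalog exclusion filters, and budget/premium counterpart
matching.

The survey design pairs every gluten-free (GF) product with two
gluten-containing (GC) products of the same category that differ in cost
tier: the cheapest candidate per kilogram ("budget") and the dearest
("premium"). Catalog hygiene mirrors a supermarket survey: byte-identical
re-listings are duplicates, and products whose label omits any of the four
core declared fields (energy, carbohydrate, protein, fat) are unusable for
recipe estimation and dropped as incomplete.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .costs import cost_per_kg
from .nutrients import (
    NUTRIENT_FIELDS,
    InvariantError,
    NutrientVector,
    validate_vector,
)

#: The seven discretionary food categories of the survey.
CATEGORIES: tuple[str, ...] = (
    "flour/bake mix",
    "bread/bakery",
    "pasta/cereal-based",
    "cereals",
    "cookies/cakes",
    "snacks",
    "convenience",
)

#: Declared fields a product must carry to be usable for estimation.
CORE_DECLARED_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "carbohydrate_g",
    "protein_g",
    "fat_g",
)


class MatchingError(ValueError):
    """Raised when a GF product cannot be matched with two counterparts."""


@dataclass(frozen=True)
class IngredientRecord:
    """One reference ingredient with its per-100 g raw composition."""

    ingredient_id: str
    name: str
    composition: NutrientVector


class CompositionTable:
    """Keyed lookup table of reference ingredients (emulates BLS/OeNWT)."""

    def __init__(self, records: Iterable[IngredientRecord]):
        self._records: dict[str, IngredientRecord] = {}
        for rec in records:
            if rec.ingredient_id in self._records:
                raise InvariantError(
                    f"duplicate ingredient_id {rec.ingredient_id!r}"
                )
            self._records[rec.ingredient_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, ingredient_id: str) -> bool:
        return ingredient_id in self._records

    def __getitem__(self, ingredient_id: str) -> IngredientRecord:
        try:
            return self._records[ingredient_id]
        except KeyError:
            raise KeyError(f"unknown ingredient_id {ingredient_id!r}") from None

    def __iter__(self) -> Iterator[IngredientRecord]:
        return iter(self._records.values())

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self:
            row: dict[str, object] = {
                "ingredient_id": rec.ingredient_id,
                "name": rec.name,
            }
            row.update(rec.composition.as_dict())
            rows.append(row)
        return pd.DataFrame(rows, columns=["ingredient_id", "name", *NUTRIENT_FIELDS])


@dataclass(frozen=True)
class FoodLabel:
    """A packaged product as read off its label.

    ``ingredients_desc`` lists ingredient ids in descending order of
    amount, exactly as printed; quantities are not given. ``declared`` is
    the partial nutrient panel the label prints (energy + macros).
    ``pooled_weight`` is 2 for rows that represent the pooled mean of two
    very similar products and 1 otherwise.
    """

    product_id: str
    name: str
    category: str
    gluten_free: bool
    ingredients_desc: tuple[str, ...]
    declared: NutrientVector
    price_eur: float
    package_mass_g: float
    pooled_weight: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingredients_desc", tuple(self.ingredients_desc))
        if not self.ingredients_desc:
            raise InvariantError(f"{self.product_id}: empty ingredient list")
        if self.category not in CATEGORIES:
            raise InvariantError(
                f"{self.product_id}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.price_eur <= 0:
            raise InvariantError(f"{self.product_id}: price_eur must be > 0")
        if self.package_mass_g <= 0:
            raise InvariantError(f"{self.product_id}: package_mass_g must be > 0")
        if self.pooled_weight < 1:
            raise InvariantError(f"{self.product_id}: pooled_weight must be >= 1")
        try:
            validate_vector(self.declared)
        except InvariantError as exc:
            raise InvariantError(f"{self.product_id}: {exc}") from None

    @property
    def cost_eur_per_kg(self) -> float:
        return cost_per_kg(self.price_eur, self.package_mass_g)

    def declared_complete(self) -> bool:
        return all(
            not self.declared.is_missing(f) for f in CORE_DECLARED_FIELDS
        )


@dataclass(frozen=True)
class MatchedSet:
    """One GF product with its budget and premium GC counterparts."""

    gf: FoodLabel
    budget_counterpart: FoodLabel
    premium_counterpart: FoodLabel

    def __post_init__(self) -> None:
        for c in (self.budget_counterpart, self.premium_counterpart):
            if c.category != self.gf.category:
                raise InvariantError(
                    f"counterpart {c.product_id} category {c.category!r} "
                    f"differs from GF category {self.gf.category!r}"
                )
            if c.gluten_free:
                raise InvariantError(
                    f"counterpart {c.product_id} is flagged gluten-free"
                )
        if (
            self.budget_counterpart.cost_eur_per_kg
            > self.premium_counterpart.cost_eur_per_kg
        ):
            raise InvariantError("budget counterpart costs more than premium")


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for the duplicate/incomplete exclusion step."""

    n_identified: int
    n_duplicates: int
    n_incomplete: int
    n_retained: int
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained != self.n_identified - self.n_duplicates - self.n_incomplete:
            raise InvariantError("exclusion counts do not reconcile")


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


def _panel_key(v: NutrientVector) -> tuple:
    return tuple(v.as_dict().items())


def apply_exclusions(
    catalog: Sequence[FoodLabel],
) -> tuple[list[FoodLabel], ExclusionReport]:
    """Drop duplicates, then incomplete products, keeping first occurrences.

    A duplicate shares a whitespace/case-normalised name *and* an identical
    declared panel with an earlier product. A product is incomplete when any
    of declared energy, carbohydrate, protein or fat is missing.
    """
    kept: list[FoodLabel] = []
    reasons: dict[str, str] = {}
    seen: set[tuple] = set()
    n_dup = n_inc = 0
    for label in catalog:
        key = (_normalize_name(label.name), _panel_key(label.declared))
        if key in seen:
            n_dup += 1
            reasons[label.product_id] = "duplicate"
            continue
        seen.add(key)
        if not label.declared_complete():
            n_inc += 1
            missing = [
                f for f in CORE_DECLARED_FIELDS if label.declared.is_missing(f)
            ]
            reasons[label.product_id] = f"incomplete: missing {', '.join(missing)}"
            continue
        kept.append(label)
    report = ExclusionReport(
        n_identified=len(catalog),
        n_duplicates=n_dup,
        n_incomplete=n_inc,
        n_retained=len(kept),
        reasons=reasons,
    )
    return kept, report


def match_counterparts(gf: FoodLabel, pool: Sequence[FoodLabel]) -> MatchedSet:
    """Pick the cheapest and dearest same-category GC products per kg.

    Ties in cost/kg break deterministically by ascending product name, so
    the result is invariant under permutations of the pool.
    """
    candidates = [
        p for p in pool if p.category == gf.category and not p.gluten_free
    ]
    if len(candidates) < 2:
        raise MatchingError(
            f"need >=2 gluten-containing candidates in category "
            f"{gf.category!r}, found {len(candidates)}"
        )
    ranked = sorted(candidates, key=lambda p: (p.cost_eur_per_kg, p.name))
    return MatchedSet(
        gf=gf, budget_counterpart=ranked[0], premium_counterpart=ranked[-1]
    )
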