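"""Assembly of the GF food-composition database: full nutrient profiles
extrapolated from recipe estimates, pooling of near-identical products,
and classification against nutrient-claim thresholds.

Thresholds follow the EU-style claim definitions used in nutrient
profiling: low sodium < 120 mg/100 g, high sodium > 500 mg/100 g, high
fiber > 6 g/100 g — all strict inequalities, so a product sitting exactly
on a threshold carries no tag. Pooled rows (the mean of two very similar
products) count as two products in every weighted summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

from .nutrients import InvariantError, NutrientVector, validate_vector

if TYPE_CHECKING:  # pragma: no cover
    from .core import CompositionTable, FoodLabel
    from .deconvolution import RecipeEstimate

#: Classification tags and the nutrient each one is decided on.
TAG_NUTRIENT = {
    "low_sodium": "sodium_mg",
    "high_sodium": "sodium_mg",
    "high_fiber": "fiber_g",
}


@dataclass(frozen=True)
class ClassificationRules:
    """Strict thresholds for nutrient-claim tags, per 100 g."""

    sodium_low_mg: float = 120.0
    sodium_high_mg: float = 500.0
    fiber_high_g: float = 6.0

    def __post_init__(self) -> None:
        if not self.sodium_low_mg < self.sodium_high_mg:
            raise InvariantError("sodium_low_mg must be below sodium_high_mg")


@dataclass(frozen=True)
class ProductProfile:
    """One database row: a product with its full 25-nutrient profile."""

    product_id: str
    category: str
    gluten_free: bool
    nutrients: NutrientVector
    pooled_weight: int = 1
    cost_eur_per_kg: float | None = None
    name: str = ""
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pooled_weight not in (1, 2):
            raise InvariantError(
                f"{self.product_id}: pooled_weight must be 1 or 2"
            )
        try:
            validate_vector(self.nutrients)
        except InvariantError as exc:
            raise InvariantError(f"{self.product_id}: {exc}") from None


def extrapolate_profile(
    estimate: "RecipeEstimate",
    label: "FoodLabel",
    table: "CompositionTable",
    *,
    allow_unconverged: bool = False,
) -> ProductProfile:
    """Turn a recipe estimate into a full nutrient profile.

    The profile is the *theoretical* composition of the estimated recipe —
    label-declared values are the fit target, never substituted into the
    output, so declared and extrapolated nutrients come from one coherent
    recipe model.
    """
    if not estimate.converged and not allow_unconverged:
        raise ValueError(
            f"{label.product_id}: estimate did not converge; pass "
            "allow_unconverged=True to extrapolate anyway"
        )
    return ProductProfile(
        product_id=label.product_id,
        name=label.name,
        category=label.category,
        gluten_free=label.gluten_free,
        nutrients=estimate.theoretical,
        pooled_weight=label.pooled_weight,
        cost_eur_per_kg=label.cost_eur_per_kg,
    )


def pool_products(a: ProductProfile, b: ProductProfile) -> ProductProfile:
    """Pool two very similar products into one weight-2 database row.

    Nutrient-wise arithmetic mean; a nutrient missing in either input is
    missing in the pooled row. Cost is averaged when both are known.
    """
    if a.category != b.category:
        raise InvariantError(
            f"cannot pool across categories ({a.category!r} vs {b.category!r})"
        )
    if a.gluten_free != b.gluten_free:
        raise InvariantError("cannot pool across the gluten-free flag")
    pooled = {}
    for name in a.nutrients.as_dict():
        va, vb = a.nutrients.get(name), b.nutrients.get(name)
        pooled[name] = None if va is None or vb is None else (va + vb) / 2.0
    cost = None
    if a.cost_eur_per_kg is not None and b.cost_eur_per_kg is not None:
        cost = (a.cost_eur_per_kg + b.cost_eur_per_kg) / 2.0
    return ProductProfile(
        product_id=f"{a.product_id}+{b.product_id}",
        name=f"{a.name} / {b.name}".strip(" /"),
        category=a.category,
        gluten_free=a.gluten_free,
        nutrients=NutrientVector.from_mapping(pooled),
        pooled_weight=2,
        cost_eur_per_kg=cost,
    )


def classify(
    profile: ProductProfile, rules: ClassificationRules | None = None
) -> set[str]:
    """Return the set of claim tags the profile earns (strict thresholds).

    A tag whose deciding nutrient is missing is *undetermined* and simply
    absent here; use :func:`is_determinable` to distinguish "not tagged"
    from "cannot tell" (prevalence denominators need that distinction).
    """
    rules = rules or ClassificationRules()
    tags: set[str] = set()
    sodium = profile.nutrients.sodium_mg
    if sodium is not None:
        if sodium < rules.sodium_low_mg:
            tags.add("low_sodium")
        if sodium > rules.sodium_high_mg:
            tags.add("high_sodium")
    fiber = profile.nutrients.fiber_g
    if fiber is not None and fiber > rules.fiber_high_g:
        tags.add("high_fiber")
    return tags


def is_determinable(profile: ProductProfile, tag: str) -> bool:
    if tag not in TAG_NUTRIENT:
        raise KeyError(f"unknown tag {tag!r}")
    return not profile.nutrients.is_missing(TAG_NUTRIENT[tag])


def prevalence(
    profiles: Sequence[ProductProfile],
    tag: str,
    rules: ClassificationRules | None = None,
) -> float | None:
    """Pooled-weight prevalence of a tag, in percent of determinable products.

    Returns ``None`` when no product is determinable for the tag.
    """
    rules = rules or ClassificationRules()
    num = den = 0
    for p in profiles:
        if not is_determinable(p, tag):
            continue
        den += p.pooled_weight
        if tag in classify(p, rules):
            num += p.pooled_weight
    if den == 0:
        return None
    return 100.0 * num / den
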