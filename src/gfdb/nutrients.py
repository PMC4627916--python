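"""Nutrient schema and the per-100 g nutrient vector.

Everything in this package is expressed per 100 g edible portion in raw
form. A nutrient value of ``None`` means *missing from the source table*,
which is deliberately distinct from a true zero: reference food-composition
databases record both, and missing values must propagate through recipe
arithmetic and be excluded from group means (with reduced n) rather than
silently counted as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace
from typing import Iterator, Mapping

#: Canonical nutrient column order: energy, then g/100 g, mg/100 g, ug/100 g.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "water_g",
    "carbohydrate_g",
    "sugar_g",
    "protein_g",
    "fat_g",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "fiber_g",
    "cholesterol_mg",
    "sodium_mg",
    "potassium_mg",
    "calcium_mg",
    "phosphorus_mg",
    "iron_mg",
    "zinc_mg",
    "vitE_mg",
    "vitC_mg",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_mg",
    "vitD_ug",
    "retinol_ug",
    "bcarotene_ug",
)

#: The macronutrient panel a label declares (besides energy).
MACRO_PANEL: tuple[str, ...] = (
    "carbohydrate_g",
    "sugar_g",
    "protein_g",
    "fat_g",
    "sfa_g",
    "fiber_g",
)

#: Absolute slack (g/100 g) for consistency checks between label-rounded
#: values: each macro is rounded to 0.1 g, so two of them may disagree by
#: up to 0.1 g without any real inconsistency.
ROUNDING_SLACK_G = 0.1


class InvariantError(ValueError):
    """A nutrient vector or domain object violates a structural invariant."""


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class NutrientVector:
    """Amounts of the 25 tracked nutrients per 100 g; ``None`` = missing."""

    energy_kcal: float | None = None
    water_g: float | None = None
    carbohydrate_g: float | None = None
    sugar_g: float | None = None
    protein_g: float | None = None
    fat_g: float | None = None
    sfa_g: float | None = None
    mufa_g: float | None = None
    pufa_g: float | None = None
    fiber_g: float | None = None
    cholesterol_mg: float | None = None
    sodium_mg: float | None = None
    potassium_mg: float | None = None
    calcium_mg: float | None = None
    phosphorus_mg: float | None = None
    iron_mg: float | None = None
    zinc_mg: float | None = None
    vitE_mg: float | None = None
    vitC_mg: float | None = None
    thiamin_mg: float | None = None
    riboflavin_mg: float | None = None
    niacin_mg: float | None = None
    vitD_ug: float | None = None
    retinol_ug: float | None = None
    bcarotene_ug: float | None = None

    def __post_init__(self) -> None:
        # Normalise NaN to None so "missing" has a single representation.
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and _is_missing(v):
                object.__setattr__(self, f.name, None)
            elif v is not None:
                object.__setattr__(self, f.name, float(v))

    def get(self, name: str) -> float | None:
        if name not in NUTRIENT_FIELDS:
            raise KeyError(name)
        return getattr(self, name)

    def is_missing(self, name: str) -> bool:
        return self.get(name) is None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in NUTRIENT_FIELDS}

    def present(self) -> Iterator[tuple[str, float]]:
        for name in NUTRIENT_FIELDS:
            v = getattr(self, name)
            if v is not None:
                yield name, v

    def replace(self, **changes: float | None) -> "NutrientVector":
        return replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float | None]) -> "NutrientVector":
        unknown = set(mapping) - set(NUTRIENT_FIELDS)
        if unknown:
            raise KeyError(f"unknown nutrient fields: {sorted(unknown)}")
        return cls(**{k: mapping[k] for k in mapping})


def validate_vector(v: NutrientVector, *, rounding_slack: float = ROUNDING_SLACK_G) -> None:
    """Check structural invariants, raising :class:`InvariantError`.

    Nonnegativity and sugar <= carbohydrate (within label-rounding slack)
    are hard errors. The fatty-acid split check (SFA+MUFA+PUFA within 5 %
    of total fat) is a warning only: published composition tables are known
    to violate it for individual rows.
    """
    for name, value in v.present():
        if value < 0:
            raise InvariantError(f"{name} is negative ({value})")
    sugar, carb = v.sugar_g, v.carbohydrate_g
    if sugar is not None and carb is not None and sugar > carb + rounding_slack + 1e-9:
        raise InvariantError(
            f"sugar_g ({sugar}) exceeds carbohydrate_g ({carb})"
        )
    fat = v.fat_g
    parts = [v.sfa_g, v.mufa_g, v.pufa_g]
    if fat is not None and all(p is not None for p in parts):
        total = sum(parts)  # type: ignore[arg-type]
        if total > fat * 1.05 + 3 * 0.05 + 1e-9:
            warnings.warn(
                f"fatty-acid split {total:.2f} g exceeds total fat {fat:.2f} g "
                "by more than rounding slack",
                stacklevel=2,
            )
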