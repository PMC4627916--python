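"""Delimited-text readers and writers for composition tables, product
catalogs, and the packaged GF survey fixtures.

File dialects
-------------
Composition table: CSV/TSV, UTF-8, header row, columns
``ingredient_id,name,<25 nutrient columns>`` in canonical order. An empty
or unparseable numeric cell is read as *missing*, never as 0.

Product catalog: CSV/TSV with columns ``product_id,name,category,
gluten_free,ingredients,declared_energy_kcal,declared_carb_g,
declared_sugar_g,declared_protein_g,declared_fat_g,declared_sfa_g,
declared_fiber_g,price_eur,package_mass_g,pooled_weight``; the
``ingredients`` cell is a semicolon-separated id list in descending order
of amount.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import IO, Iterable, Literal

import pandas as pd

from .core import CompositionTable, FoodLabel, IngredientRecord
from .database import ProductProfile
from .nutrients import NUTRIENT_FIELDS, InvariantError, NutrientVector

_CATALOG_DECLARED = {
    "declared_energy_kcal": "energy_kcal",
    "declared_carb_g": "carbohydrate_g",
    "declared_sugar_g": "sugar_g",
    "declared_protein_g": "protein_g",
    "declared_fat_g": "fat_g",
    "declared_sfa_g": "sfa_g",
    "declared_fiber_g": "fiber_g",
}

_CATALOG_COLUMNS = (
    "product_id",
    "name",
    "category",
    "gluten_free",
    "ingredients",
    *_CATALOG_DECLARED,
    "price_eur",
    "package_mass_g",
    "pooled_weight",
)


def _read_frame(source: str | Path | IO[str], required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvariantError(f"missing mandatory columns: {missing}")
    return df


def _num(cell: str | None) -> float | None:
    """Parse one numeric cell; anything unparseable becomes missing."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    value = pd.to_numeric(pd.Series([cell]), errors="coerce").iloc[0]
    return None if pd.isna(value) else float(value)


def read_composition_table(source: str | Path | IO[str]) -> CompositionTable:
    """Read a reference ingredient table; duplicate ids are a hard error."""
    df = _read_frame(source, ("ingredient_id", "name", *NUTRIENT_FIELDS))
    dup = df["ingredient_id"][df["ingredient_id"].duplicated()].unique()
    if len(dup):
        raise InvariantError(f"duplicate ingredient_id values: {sorted(dup)}")
    records = []
    for _, row in df.iterrows():
        comp = NutrientVector.from_mapping(
            {f: _num(row[f]) for f in NUTRIENT_FIELDS}
        )
        records.append(
            IngredientRecord(
                ingredient_id=str(row["ingredient_id"]),
                name=str(row["name"]),
                composition=comp,
            )
        )
    return CompositionTable(records)


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_product_catalog(
    source: str | Path | IO[str],
    table: CompositionTable | None = None,
    on_unresolved: Literal["error", "drop"] = "error",
) -> list[FoodLabel]:
    """Read a product catalog, optionally resolving ingredients.

    With a composition ``table`` and ``on_unresolved="error"`` any listed
    ingredient absent from the table raises, naming product and ingredient;
    with ``"drop"`` the offending product is skipped with a warning-free
    drop (the caller gets fewer labels back).
    """
    df = _read_frame(source, _CATALOG_COLUMNS)
    labels: list[FoodLabel] = []
    for _, row in df.iterrows():
        ingredients = tuple(
            tok.strip() for tok in str(row["ingredients"]).split(";") if tok.strip()
        )
        if table is not None:
            unresolved = [i for i in ingredients if i not in table]
            if unresolved:
                if on_unresolved == "error":
                    raise InvariantError(
                        f"product {row['product_id']!r}: unresolved "
                        f"ingredient(s) {unresolved}"
                    )
                continue
        declared = NutrientVector.from_mapping(
            {nutrient: _num(row[col]) for col, nutrient in _CATALOG_DECLARED.items()}
        )
        pooled = _num(row["pooled_weight"])
        labels.append(
            FoodLabel(
                product_id=str(row["product_id"]),
                name=str(row["name"]),
                category=str(row["category"]),
                gluten_free=str(row["gluten_free"]).strip().lower()
                in {"true", "1", "yes"},
                ingredients_desc=ingredients,
                declared=declared,
                price_eur=float(row["price_eur"]),
                package_mass_g=float(row["package_mass_g"]),
                pooled_weight=int(pooled) if pooled is not None else 1,
            )
        )
    return labels


def write_product_catalog(labels: Iterable[FoodLabel], path: str | Path) -> None:
    rows = []
    for lb in labels:
        row: dict[str, object] = {
            "product_id": lb.product_id,
            "name": lb.name,
            "category": lb.category,
            "gluten_free": lb.gluten_free,
            "ingredients": ";".join(lb.ingredients_desc),
        }
        for col, nutrient in _CATALOG_DECLARED.items():
            row[col] = lb.declared.get(nutrient)
        row["price_eur"] = lb.price_eur
        row["package_mass_g"] = lb.package_mass_g
        row["pooled_weight"] = lb.pooled_weight
        rows.append(row)
    pd.DataFrame(rows, columns=list(_CATALOG_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged survey fixtures (58 rows; 5 pooled rows carry weight 2)
# ---------------------------------------------------------------------------

def _data_path(filename: str):
    return importlib.resources.files("gfdb.data").joinpath(filename)


def load_table1() -> pd.DataFrame:
    """Macronutrient survey table (per 100 g) for the 63 GF products."""
    with _data_path("table1_gf_macros.csv").open() as fh:
        return pd.read_csv(fh)


def load_table2() -> pd.DataFrame:
    """Micronutrient survey table (per 100 g) for the 63 GF products."""
    with _data_path("table2_gf_micros.csv").open() as fh:
        return pd.read_csv(fh)


def load_gf_profiles() -> list[ProductProfile]:
    """Join the two survey tables into full product profiles.

    Water is not reported in the survey tables and stays missing. No cost
    data is packaged, so ``cost_eur_per_kg`` is ``None``. The handful of
    published rows whose printed fatty-acid split exceeds total fat are
    known data oddities; their soft-check warnings are suppressed here.
    """
    t1 = load_table1().set_index("product_id")
    t2 = load_table2().set_index("product_id")
    if not t1.index.equals(t2.index):
        raise InvariantError("survey fixture tables disagree on product ids")
    profiles = []
    for pid in t1.index:
        r1, r2 = t1.loc[pid], t2.loc[pid]
        if r1["pooled_weight"] != r2["pooled_weight"]:
            raise InvariantError(f"{pid}: pooled_weight mismatch between tables")
        amounts = {
            f: r1[f] for f in NUTRIENT_FIELDS if f in t1.columns
        }
        amounts.update({f: r2[f] for f in NUTRIENT_FIELDS if f in t2.columns})
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="fatty-acid split")
            profiles.append(
                ProductProfile(
                    product_id=str(pid),
                    name=str(r1["name"]),
                    category=str(r1["category"]),
                    gluten_free=True,
                    nutrients=NutrientVector.from_mapping(amounts),
                    pooled_weight=int(r1["pooled_weight"]),
                    cost_eur_per_kg=None,
                )
            )
    return profiles
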