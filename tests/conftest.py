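import numpy as np
import pytest

from gfdb import (
    CompositionTable,
    FoodLabel,
    IngredientRecord,
    NutrientVector,
    SynthConfig,
    generate_ingredient_table,
    load_gf_profiles,
)


@pytest.fixture(scope="session")
def toy_table() -> CompositionTable:
    """Three hand-built ingredients with round numbers for arithmetic oracles.

    Energies are consistent with the default conversion factors
    (4/4/9 kcal per g, fiber 2), e.g. flour: 4*80 + 4*7 + 9*1.5 + 2*3 = 367.5.
    """
    flour = NutrientVector(
        energy_kcal=367.5, water_g=8.5, carbohydrate_g=80.0, sugar_g=1.0,
        protein_g=7.0, fat_g=1.5, sfa_g=0.3, mufa_g=0.4, pufa_g=0.7,
        fiber_g=3.0, sodium_mg=2.0, potassium_mg=150.0, iron_mg=1.2,
        zinc_mg=0.9, calcium_mg=30.0, phosphorus_mg=100.0,
    )
    sugar = NutrientVector(
        energy_kcal=400.0, water_g=0.0, carbohydrate_g=100.0, sugar_g=100.0,
        protein_g=0.0, fat_g=0.0, sfa_g=0.0, mufa_g=0.0, pufa_g=0.0,
        fiber_g=0.0, sodium_mg=0.0, potassium_mg=2.0,
    )
    oil = NutrientVector(
        energy_kcal=900.0, water_g=0.0, carbohydrate_g=0.0, sugar_g=0.0,
        protein_g=0.0, fat_g=100.0, sfa_g=15.0, mufa_g=60.0, pufa_g=20.0,
        fiber_g=0.0, sodium_mg=0.0,
    )
    return CompositionTable(
        [
            IngredientRecord("flour", "rice flour", flour),
            IngredientRecord("sugar", "sucrose", sugar),
            IngredientRecord("oil", "sunflower oil", oil),
        ]
    )


def make_label(
    product_id="p1",
    name="test product",
    category="flour/bake mix",
    gluten_free=True,
    ingredients=("flour",),
    declared=None,
    price_eur=2.0,
    package_mass_g=500.0,
    pooled_weight=1,
) -> FoodLabel:
    declared = declared if declared is not None else NutrientVector(
        energy_kcal=367.5, carbohydrate_g=80.0, sugar_g=1.0,
        protein_g=7.0, fat_g=1.5, sfa_g=0.3, fiber_g=3.0,
    )
    return FoodLabel(
        product_id=product_id, name=name, category=category,
        gluten_free=gluten_free, ingredients_desc=tuple(ingredients),
        declared=declared, price_eur=price_eur,
        package_mass_g=package_mass_g, pooled_weight=pooled_weight,
    )


@pytest.fixture(scope="session")
def synth_table() -> CompositionTable:
    return generate_ingredient_table(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def gf_profiles():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # survey fat-split rows
        return load_gf_profiles()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
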