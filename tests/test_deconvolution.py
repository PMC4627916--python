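"""Recipe deconvolution: mixture arithmetic, energy conversion, the
constrained solver against its grid oracle, and parameter recovery."""

import numpy as np
import pytest

from gfdb import (
    EnergyFactors,
    NutrientVector,
    SynthConfig,
    brute_force_recipe,
    energy_from_macros,
    estimate_recipe,
    estimation_precision,
    generate_recipe,
    render_label,
    theoretical_composition,
)
from gfdb.deconvolution import EstimateOptions, _fit_system
from gfdb.nutrients import InvariantError

from conftest import make_label


class TestTheoreticalComposition:
    def test_single_ingredient_identity(self, toy_table):
        theo = theoretical_composition([("flour", 100.0)], toy_table)
        assert theo.as_dict() == toy_table["flour"].composition.as_dict()

    def test_fifty_fifty_is_arithmetic_mean(self, toy_table):
        theo = theoretical_composition(
            [("flour", 50.0), ("sugar", 50.0)], toy_table
        )
        f = toy_table["flour"].composition
        s = toy_table["sugar"].composition
        for name, value in theo.present():
            fv, sv = f.get(name), s.get(name)
            if fv is not None and sv is not None:
                assert value == pytest.approx((fv + sv) / 2)

    def test_60_30_10_weighted_sum_oracle(self, toy_table):
        theo = theoretical_composition(
            [("flour", 60.0), ("sugar", 30.0), ("oil", 10.0)], toy_table
        )
        # hand-computed: 0.6*flour + 0.3*sugar + 0.1*oil
        assert theo.carbohydrate_g == pytest.approx(0.6 * 80 + 0.3 * 100)
        assert theo.sugar_g == pytest.approx(0.6 * 1 + 0.3 * 100)
        assert theo.protein_g == pytest.approx(4.2)
        assert theo.fat_g == pytest.approx(0.6 * 1.5 + 0.1 * 100)
        assert theo.energy_kcal == pytest.approx(
            0.6 * 367.5 + 0.3 * 400 + 0.1 * 900
        )

    def test_linearity_in_mixtures(self, toy_table):
        p = [("flour", 70.0), ("sugar", 20.0)]
        q = [("flour", 30.0), ("sugar", 60.0)]
        alpha = 0.25
        mix = [
            ("flour", alpha * 70 + (1 - alpha) * 30),
            ("sugar", alpha * 20 + (1 - alpha) * 60),
        ]
        tp = theoretical_composition(p, toy_table)
        tq = theoretical_composition(q, toy_table)
        tm = theoretical_composition(mix, toy_table)
        for name, value in tm.present():
            pv, qv = tp.get(name), tq.get(name)
            if pv is not None and qv is not None:
                assert value == pytest.approx(alpha * pv + (1 - alpha) * qv)

    def test_missing_propagates_only_from_contributors(self, toy_table):
        # oil has no iron value; flour does
        theo = theoretical_composition(
            [("flour", 50.0), ("oil", 50.0)], toy_table
        )
        assert theo.is_missing("iron_mg")
        theo2 = theoretical_composition(
            [("flour", 100.0), ("oil", 0.0)], toy_table
        )
        assert not theo2.is_missing("iron_mg")

    def test_water_residual_credited_to_water(self, toy_table):
        theo = theoretical_composition(
            [("flour", 90.0)], toy_table, water_residual_pct=10.0
        )
        assert theo.water_g == pytest.approx(0.9 * 8.5 + 10.0)

    def test_unresolved_id_errors(self, toy_table):
        with pytest.raises(KeyError):
            theoretical_composition([("nope", 100.0)], toy_table)


class TestEnergyFromMacros:
    def test_all_zero_vector(self):
        v = NutrientVector(carbohydrate_g=0, protein_g=0, fat_g=0, fiber_g=0)
        assert energy_from_macros(v) == 0.0

    def test_single_term(self):
        v = NutrientVector(carbohydrate_g=10, protein_g=0, fat_g=0)
        assert energy_from_macros(v) == pytest.approx(40.0)

    def test_fiber_term_omitted_when_missing_or_zero_factor(self):
        v = NutrientVector(carbohydrate_g=10, protein_g=5, fat_g=2, fiber_g=4)
        assert energy_from_macros(v) == pytest.approx(40 + 20 + 18 + 8)
        no_fiber = v.replace(fiber_g=None)
        assert energy_from_macros(no_fiber) == pytest.approx(78.0)
        f0 = EnergyFactors(fiber=0.0)
        assert energy_from_macros(v, f0) == pytest.approx(78.0)

    def test_missing_required_field_errors(self):
        with pytest.raises(InvariantError, match="protein"):
            energy_from_macros(NutrientVector(carbohydrate_g=10, fat_g=1))

    def test_survey_flour_row_consistent_within_7pct(self):
        # printed GF flour panel: the conversion convention is unstated, so
        # only a tolerance check against the printed 345.5 kcal is possible
        v = NutrientVector(
            carbohydrate_g=77.6, protein_g=3.7, fat_g=1.7, fiber_g=3.8
        )
        assert energy_from_macros(v) == pytest.approx(345.5, rel=0.07)


class TestEstimationPrecision:
    def test_identical_vectors_give_100(self):
        v = NutrientVector(energy_kcal=100, protein_g=5.0)
        assert estimation_precision(v, v) == {
            "energy_kcal": pytest.approx(100.0),
            "protein_g": pytest.approx(100.0),
        }

    def test_direct_ratio(self):
        theo = NutrientVector(protein_g=9.3)
        label = NutrientVector(protein_g=10.0)
        assert estimation_precision(theo, label)["protein_g"] == pytest.approx(93.0)

    def test_zero_or_missing_label_excluded(self):
        theo = NutrientVector(protein_g=9.3, fat_g=1.0)
        label = NutrientVector(protein_g=0.0, fat_g=None, sugar_g=2.0)
        assert estimation_precision(theo, label) == {}


class TestEstimateRecipe:
    def test_one_ingredient_noise_free(self, toy_table):
        label = make_label(ingredients=("flour",))
        est = estimate_recipe(label, toy_table)
        assert est.converged
        assert est.proportions[0][1] == pytest.approx(100.0, abs=1e-6)
        assert est.water_residual_pct == pytest.approx(0.0, abs=1e-6)
        for value in est.precision.values():
            assert value == pytest.approx(100.0, abs=1e-4)

    def test_two_ingredient_60_40_recovery(self, toy_table):
        declared = NutrientVector(
            energy_kcal=0.6 * 367.5 + 0.4 * 400,
            carbohydrate_g=0.6 * 80 + 0.4 * 100,
            sugar_g=0.6 * 1 + 0.4 * 100,
            protein_g=0.6 * 7,
            fat_g=0.6 * 1.5,
            sfa_g=0.6 * 0.3,
            fiber_g=0.6 * 3,
        )
        label = make_label(ingredients=("flour", "sugar"), declared=declared)
        est = estimate_recipe(label, toy_table)
        assert est.converged and est.uniqueness_flag == "unique"
        assert est.proportions[0][1] == pytest.approx(60.0, abs=1.0)
        assert est.proportions[1][1] == pytest.approx(40.0, abs=1.0)
        # independent 0.1 % grid oracle agrees on the optimum
        grid = brute_force_recipe(label, toy_table, step=0.1)
        assert grid.proportions[0][1] == pytest.approx(60.0, abs=0.1)
        assert grid.proportions[1][1] == pytest.approx(40.0, abs=0.1)

    def test_ordering_constraint_binds(self, toy_table):
        # panel of a 30/70 flour/sugar blend, but the label claims flour
        # is the main ingredient: the fit must keep p1 >= p2
        declared = NutrientVector(
            energy_kcal=0.3 * 367.5 + 0.7 * 400,
            carbohydrate_g=0.3 * 80 + 0.7 * 100,
            sugar_g=0.3 * 1 + 0.7 * 100,
            protein_g=0.3 * 7,
            fat_g=0.3 * 1.5,
        )
        label = make_label(ingredients=("flour", "sugar"), declared=declared)
        est = estimate_recipe(label, toy_table)
        p = [pct for _, pct in est.proportions]
        assert p[0] >= p[1] - 1e-9

    def test_infeasible_label_is_diagnostic_not_crash(self, toy_table):
        # energy wildly inconsistent with any mixture of these ingredients
        declared = NutrientVector(
            energy_kcal=2000.0, carbohydrate_g=10.0, protein_g=1.0, fat_g=1.0
        )
        label = make_label(ingredients=("flour", "sugar"), declared=declared)
        est = estimate_recipe(label, toy_table)
        assert est.objective_value > 0.1

    def test_under_determined_flagged(self, synth_table):
        # two sugar-family ingredients are collinear over the macro panel
        sugars = [
            r.ingredient_id
            for r in synth_table
            if r.composition.sugar_g == r.composition.carbohydrate_g
            and r.composition.protein_g == 0.0
        ][:2]
        assert len(sugars) == 2
        blend = theoretical_composition(
            [(sugars[0], 60.0), (sugars[1], 40.0)], synth_table
        )
        label = make_label(
            ingredients=tuple(sugars),
            declared=NutrientVector(
                energy_kcal=blend.energy_kcal,
                carbohydrate_g=blend.carbohydrate_g,
                sugar_g=blend.sugar_g,
                protein_g=blend.protein_g,
                fat_g=blend.fat_g,
            ),
        )
        est = estimate_recipe(label, synth_table)
        assert est.uniqueness_flag == "under-determined"
        assert est.face_dim >= 1

    def test_monotone_and_bounded_on_random_cases(self, synth_table):
        cfg = SynthConfig(seed=5)
        rng = np.random.default_rng(42)
        for i in range(25):
            k = int(rng.integers(2, 9))
            truth = generate_recipe(k, synth_table, 900 + i)
            label = render_label(truth, synth_table, cfg)
            est = estimate_recipe(label, synth_table)
            p = [pct for _, pct in est.proportions]
            assert all(p[j] >= p[j + 1] - 1e-6 for j in range(len(p) - 1))
            assert -1e-9 <= sum(p) <= 100 + 1e-6


class TestBruteForceOracle:
    def test_k1_grid(self, toy_table):
        label = make_label(ingredients=("flour",))
        est = brute_force_recipe(label, toy_table, step=1.0)
        assert est.proportions[0][1] == pytest.approx(100.0)

    def test_coarse_grid_enumeration_k2(self, toy_table):
        label = make_label(ingredients=("flour", "sugar"))
        est = brute_force_recipe(label, toy_table, step=50.0)
        # ordered pairs on the 50 % grid with sum <= 100:
        # (0,0), (50,0), (50,50), (100,0)
        assert est.n_iterations == 4

    def test_guards(self, toy_table):
        label = make_label(ingredients=("flour", "sugar", "oil", "flour", "sugar"))
        with pytest.raises(ValueError, match="k <= 4"):
            brute_force_recipe(label, toy_table, step=10.0)
        with pytest.raises(ValueError, match="step"):
            brute_force_recipe(make_label(),
                               toy_table, step=0.01)

    def test_solver_beats_grid_k2_and_k3(self, synth_table):
        cfg = SynthConfig(seed=5)
        step = 0.5
        for i, k in enumerate([2, 2, 3, 3, 3]):
            truth = generate_recipe(k, synth_table, 700 + i)
            label = render_label(truth, synth_table, cfg)
            cont = estimate_recipe(label, synth_table)
            grid = brute_force_recipe(label, synth_table, step=step)
            # grid optimum cannot beat the continuous optimum by more than
            # the grid-resolution slack around the continuous solution
            B, b, _ = _fit_system(label, synth_table, EstimateOptions())
            slack = (np.linalg.norm(B, 2) * step * np.sqrt(k)) ** 2
            assert cont.objective_value <= grid.objective_value + 1e-9
            assert grid.objective_value <= cont.objective_value + slack


class TestRecoverySuite:
    def test_recovery_within_half_point_on_identifiable_cases(self, synth_table):
        """Noise-free, rounding-free labels with linearly independent
        ingredient signatures must reproduce the true proportions."""
        cfg = SynthConfig(seed=1, label_rounding=False, noise_sd_rel=0.0)
        rng = np.random.default_rng(2024)
        checked = 0
        for i in range(160):
            k = int(rng.integers(2, 7))
            truth = generate_recipe(k, synth_table, 20_000 + i)
            label = render_label(truth, synth_table, cfg)
            B, _, _ = _fit_system(label, synth_table, EstimateOptions())
            if np.linalg.matrix_rank(B, tol=1e-7) < k:
                continue  # under-determined by construction; not a recovery case
            est = estimate_recipe(label, synth_table)
            tr, es = dict(truth.proportions), dict(est.proportions)
            err = max(abs(tr[q] - es[q]) for q in tr)
            assert err <= 0.5, f"case {i}: recovery error {err:.3f} pp"
            checked += 1
        assert checked >= 100
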