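"""Recipe deconvolution: back-calculate hidden ingredient proportions from
a label's descending-order ingredient list and its declared nutrient panel.

Model
-----
A packaged food is modelled as a mixture of k reference ingredients at
unknown percentages p_1 >= p_2 >= ... >= p_k >= 0 (the label lists
ingredients in descending order of amount), with sum(p) <= 100; the mass
remainder 100 - sum(p) is water/moisture added in processing and
contributes only to the water column. Every nutrient is linear in p, so
the declared panel gives the constrained weighted least-squares problem

    minimise   sum_n w_n * (theoretical_n(p) / label_n - 1)^2

over the declared nutrients n (energy computed from macros via Atwater-type
factors, plus carbohydrate, sugar, protein, fat, saturated fat and fiber
when declared and positive). Relative deviations put every nutrient on the
dimensionless scale the survey's "estimation precision" is defined on
(theoretical / label x 100 %); energy carries double weight because the
manual iteration this formalises stopped on label energy.

The feasible set (ordered sub-simplex) is convex and the objective is a
convex quadratic, so the minimum is found reliably by reparametrising to
the difference cone p_i = sum_{j>=i} d_j with d >= 0, under which the
ordering constraint becomes a plain nonnegativity bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import LinearConstraint, minimize, nnls

from .core import CompositionTable, FoodLabel
from .nutrients import MACRO_PANEL, InvariantError, NutrientVector

#: Nutrients (besides energy) that can enter the fit objective.
FIT_NUTRIENTS: tuple[str, ...] = MACRO_PANEL


@dataclass(frozen=True)
class EnergyFactors:
    """Per-gram kcal conversion factors (EU convention, fiber at 2)."""

    carbohydrate: float = 4.0
    protein: float = 4.0
    fat: float = 9.0
    fiber: float = 2.0

    def __post_init__(self) -> None:
        for name in ("carbohydrate", "protein", "fat", "fiber"):
            if getattr(self, name) < 0:
                raise InvariantError(f"energy factor {name} must be >= 0")


def energy_from_macros(
    v: NutrientVector, factors: EnergyFactors | None = None
) -> float:
    """Label-style energy (kcal/100 g) from the macronutrient panel.

    Carbohydrate, protein and fat are required; the fiber term is dropped
    when fiber is missing or its factor is configured to 0.
    """
    f = factors or EnergyFactors()
    missing = [
        n for n in ("carbohydrate_g", "protein_g", "fat_g") if v.is_missing(n)
    ]
    if missing:
        raise InvariantError(f"energy_from_macros requires {missing}")
    kcal = (
        f.carbohydrate * v.carbohydrate_g
        + f.protein * v.protein_g
        + f.fat * v.fat_g
    )
    if f.fiber > 0 and not v.is_missing("fiber_g"):
        kcal += f.fiber * v.fiber_g
    return kcal


def theoretical_composition(
    proportions: Sequence[tuple[str, float]],
    table: CompositionTable,
    water_residual_pct: float | None = None,
) -> NutrientVector:
    """Proportion-weighted nutrient vector of a recipe.

    Each nutrient is sum_i (percent_i / 100) x ingredient composition_i.
    A nutrient is missing in the output iff it is missing in any ingredient
    that actually contributes (percent > 0). ``water_residual_pct`` grams of
    added water per 100 g are credited to the water column only.
    """
    total = 0.0
    for _, pct in proportions:
        if pct < -1e-9:
            raise InvariantError(f"negative proportion {pct}")
        total += pct
    if total > 100.0 + 1e-6:
        raise InvariantError(f"proportions sum to {total} > 100")
    sums: dict[str, float] = {}
    missing: set[str] = set()
    for ingredient_id, pct in proportions:
        comp = table[ingredient_id].composition
        if pct <= 0:
            continue
        for name, value in comp.as_dict().items():
            if value is None:
                missing.add(name)
            else:
                sums[name] = sums.get(name, 0.0) + pct / 100.0 * value
    out = {
        name: (None if name in missing else sums.get(name))
        for name in set(sums) | missing
    }
    if water_residual_pct:
        if water_residual_pct < 0:
            raise InvariantError("water residual must be >= 0")
        if "water_g" not in missing:
            out["water_g"] = out.get("water_g", 0.0) + water_residual_pct
    return NutrientVector.from_mapping(out)


def estimation_precision(
    theoretical: NutrientVector, label: NutrientVector
) -> dict[str, float]:
    """Per-nutrient precision: 100 x theoretical / label, in percent.

    Entries exist only for nutrients the label declares with a value > 0
    and the theoretical vector actually carries; 100 % is a perfect match.
    """
    out: dict[str, float] = {}
    for name, declared in label.present():
        if declared <= 0:
            continue
        theo = theoretical.get(name)
        if theo is None:
            continue
        out[name] = 100.0 * theo / declared
    return out


@dataclass(frozen=True)
class RecipeEstimate:
    """Result of a recipe deconvolution."""

    proportions: tuple[tuple[str, float], ...]
    theoretical: NutrientVector
    precision: dict[str, float]
    objective_value: float
    converged: bool
    n_iterations: int
    uniqueness_flag: str  # "unique" | "under-determined"
    water_residual_pct: float
    face_dim: int = 0
    kkt_residual: float = math.nan

    def __post_init__(self) -> None:
        pcts = [pct for _, pct in self.proportions]
        if any(p < -1e-9 for p in pcts):
            raise InvariantError("estimated proportions must be >= 0")
        if any(pcts[i] < pcts[i + 1] - 1e-6 for i in range(len(pcts) - 1)):
            raise InvariantError("estimated proportions must be non-increasing")
        if sum(pcts) > 100.0 + 1e-6:
            raise InvariantError("estimated proportions exceed 100 %")


@dataclass(frozen=True)
class EstimateOptions:
    """Tunables of the deconvolution solver."""

    energy_weight: float = 2.0
    factors: EnergyFactors = field(default_factory=EnergyFactors)
    kkt_tol: float = 1e-8
    max_iterations: int = 500
    init_total_pct: float = 90.0


def _fit_system(
    label: FoodLabel, table: CompositionTable, options: EstimateOptions
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Weighted relative-deviation design matrix B and target b.

    Row n of B is sqrt(w_n)/L_n times the per-percent contribution of each
    ingredient to nutrient n; the objective is ||B p - b||^2 with
    b = sqrt(w). Missing ingredient values contribute 0 to the fit.
    """
    k = len(label.ingredients_desc)
    comps = [table[i].composition for i in label.ingredients_desc]
    f = options.factors

    def macro_row(name: str) -> np.ndarray:
        return np.array(
            [(c.get(name) or 0.0) / 100.0 for c in comps], dtype=float
        )

    rows, weights, targets, names = [], [], [], []
    energy = label.declared.energy_kcal
    if energy is not None and energy > 0:
        row = (
            f.carbohydrate * macro_row("carbohydrate_g")
            + f.protein * macro_row("protein_g")
            + f.fat * macro_row("fat_g")
            + f.fiber * macro_row("fiber_g")
        )
        rows.append(row)
        weights.append(options.energy_weight)
        targets.append(energy)
        names.append("energy_kcal")
    for name in FIT_NUTRIENTS:
        declared = label.declared.get(name)
        if declared is not None and declared > 0:
            rows.append(macro_row(name))
            weights.append(1.0)
            targets.append(declared)
            names.append(name)
    if not rows:
        raise InvariantError(
            f"{label.product_id}: no positive declared nutrients to fit"
        )
    A = np.vstack(rows)
    w = np.sqrt(np.array(weights))
    L = np.array(targets)
    B = (w / L)[:, None] * A
    b = w
    assert B.shape == (len(names), k)
    return B, b, names


def _polish_boundary(
    BM: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Sharpen an interior-point iterate sitting on the sum constraint.

    When the relaxed optimum spills past 100 %, convexity puts the true
    optimum exactly on sum(p) = 100. The barrier solver only approaches
    that face, so re-solve the equality-constrained least squares on the
    inferred free set (activating bounds as needed) and keep the result
    when it does not worsen the objective.
    """
    k = len(d)
    obj0 = float(np.sum((BM @ d - b) ** 2))
    active = d <= 1e-6 * max(1.0, float(d.max()))
    for _ in range(2 * k):
        free = ~active
        if not free.any():
            return d
        B_F, c_F = BM[:, free], c[free]
        d_part = 100.0 * c_F / (c_F @ c_F)
        N = null_space(c_F[None, :])
        if N.size:
            z, *_ = np.linalg.lstsq(B_F @ N, b - B_F @ d_part, rcond=None)
            d_F = d_part + N @ z
        else:
            d_F = d_part
        if (d_F < -1e-10).any():
            worst = np.flatnonzero(free)[int(np.argmin(d_F))]
            active[worst] = True
            continue
        d_new = np.zeros(k)
        d_new[free] = np.clip(d_F, 0.0, None)
        if float(np.sum((BM @ d_new - b) ** 2)) <= obj0 + 1e-12:
            return d_new
        return d
    return d


def _kkt_residual(
    BM: np.ndarray, b: np.ndarray, d: np.ndarray, c: np.ndarray, active_tol: float
) -> tuple[float, list[np.ndarray]]:
    """Distance of the gradient from the cone spanned by active constraints.

    Returns the residual and the normals of *strongly* active constraints
    (active with a positive multiplier). Weakly active constraints — e.g.
    a zero proportion sitting on a vertex of a flat optimal face — do not
    pin the optimum and are excluded, so the face dimension below sees
    through them.
    """
    g = 2.0 * BM.T @ (BM @ d - b)
    cols: list[np.ndarray] = []
    for j in np.flatnonzero(d <= active_tol):
        e = np.zeros(len(d))
        e[j] = 1.0
        cols.append(e)  # multiplier for d_j >= 0 adds +e_j to the gradient
    if c @ d >= 100.0 - active_tol:
        cols.append(-c.astype(float))  # sum <= 100 pushes along -c
    if not cols:
        return float(np.linalg.norm(g)), []
    A = np.column_stack(cols)
    lam, rnorm = nnls(A, g)
    dual_tol = 1e-8 * max(1.0, float(np.linalg.norm(g)))
    strong = [col for col, mult in zip(cols, lam) if mult > dual_tol]
    return float(rnorm), strong


def _face_dimension(BM: np.ndarray, strong_normals: list[np.ndarray]) -> int:
    """Dimension of the optimal face: free directions the data cannot pin."""
    if strong_normals:
        N = null_space(np.vstack(strong_normals))
    else:
        N = np.eye(BM.shape[1])
    if N.size == 0:
        return 0
    free_dim = N.shape[1]
    return free_dim - int(np.linalg.matrix_rank(BM @ N, tol=1e-8))


def estimate_recipe(
    label: FoodLabel,
    table: CompositionTable,
    options: EstimateOptions | None = None,
) -> RecipeEstimate:
    """Estimate ingredient proportions for one labelled product.

    Solves the convex ordered-simplex least-squares problem described in
    the module docstring. ``converged`` reports whether the KKT residual
    (gradient distance from the active-constraint cone, relative to the
    gradient scale) fell below ``options.kkt_tol``; an infeasible or
    contradictory label yields a diagnostic result with
    ``converged=False`` rather than an exception.
    """
    options = options or EstimateOptions()
    unresolved = [i for i in label.ingredients_desc if i not in table]
    if unresolved:
        raise KeyError(
            f"{label.product_id}: unresolved ingredient(s) {unresolved}"
        )
    k = len(label.ingredients_desc)
    B, b, _ = _fit_system(label, table, options)

    # p = M d, d >= 0 encodes the ordering; sum(p) = c . d <= 100.
    M = np.triu(np.ones((k, k)))
    c = np.arange(1, k + 1, dtype=float)
    BM = B @ M

    # Interior case (sum < 100, the rule when recipes carry a water
    # residual): plain NNLS in d-space is the exact optimum. Only when the
    # relaxed solution spills over 100 % is the general QP solver needed.
    d_relaxed, _ = nnls(BM, b)
    n_iterations = k
    if c @ d_relaxed <= 100.0 + 1e-9:
        d = d_relaxed
        objective = float(np.sum((BM @ d - b) ** 2))
    else:
        p0 = 1.0 / np.arange(1, k + 1)
        p0 *= options.init_total_pct / p0.sum()
        d0 = np.append(p0[:-1] - p0[1:], p0[-1])
        H = 2.0 * BM.T @ BM
        res = minimize(
            lambda d: float(np.sum((BM @ d - b) ** 2)),
            d0,
            jac=lambda d: 2.0 * BM.T @ (BM @ d - b),
            hess=lambda d: H,
            method="trust-constr",
            bounds=[(0.0, None)] * k,
            constraints=[LinearConstraint(c, -np.inf, 100.0)],
            options={
                "gtol": 1e-12,
                "xtol": 1e-14,
                "barrier_tol": 1e-12,
                "maxiter": options.max_iterations,
            },
        )
        d = np.clip(res.x, 0.0, None)
        total = float(c @ d)
        if total > 100.0:
            d *= 100.0 / total
        d = _polish_boundary(BM, b, c, d)
        objective = float(np.sum((BM @ d - b) ** 2))
        n_iterations = int(res.niter)
    p = M @ d
    active_tol = 1e-7 * max(1.0, float(p[0]))
    kkt, strong_normals = _kkt_residual(BM, b, d, c, active_tol)
    grad_scale = max(1.0, float(np.linalg.norm(2.0 * BM.T @ b)))
    converged = bool(kkt <= options.kkt_tol * grad_scale)
    face_dim = _face_dimension(BM, strong_normals)

    proportions = tuple(
        (iid, float(pct)) for iid, pct in zip(label.ingredients_desc, p)
    )
    residual = max(0.0, 100.0 - float(p.sum()))
    theoretical = theoretical_composition(
        proportions, table, water_residual_pct=residual
    )
    return RecipeEstimate(
        proportions=proportions,
        theoretical=theoretical,
        precision=estimation_precision(theoretical, label.declared),
        objective_value=objective,
        converged=converged,
        n_iterations=n_iterations,
        uniqueness_flag="under-determined" if face_dim > 0 else "unique",
        water_residual_pct=residual,
        face_dim=face_dim,
        kkt_residual=kkt,
    )


def brute_force_recipe(
    label: FoodLabel,
    table: CompositionTable,
    step: float,
    options: EstimateOptions | None = None,
) -> RecipeEstimate:
    """Exhaustive grid oracle over the ordered simplex (k <= 4 only).

    Enumerates every non-increasing proportion vector on the ``step``-%
    grid with sum <= 100 and returns the grid-optimal estimate under the
    same objective as :func:`estimate_recipe`. Intended as an independent
    check of the continuous solver on small problems.
    """
    options = options or EstimateOptions()
    k = len(label.ingredients_desc)
    if k > 4:
        raise ValueError("brute force is guarded to k <= 4 ingredients")
    if step < 0.1:
        raise ValueError("step must be >= 0.1 %")
    B, b, _ = _fit_system(label, table, options)

    grid = np.arange(0.0, 100.0 + step / 2, step)
    best_obj = math.inf
    best_p: np.ndarray | None = None
    n_points = 0
    ties = 0

    def recurse(prefix: list[float], remaining: float) -> None:
        nonlocal best_obj, best_p, n_points, ties
        depth = len(prefix)
        cap = min(prefix[-1], remaining) if prefix else min(100.0, remaining)
        values = grid[grid <= cap + 1e-9]
        if depth == k - 1:
            pts = np.tile(np.array(prefix), (len(values), 1))
            pts = np.column_stack([pts, values]) if depth else values[:, None]
            objs = np.sum((pts @ B.T - b) ** 2, axis=1)
            n_points += len(values)
            i = int(np.argmin(objs))
            if objs[i] < best_obj - 1e-12:
                best_obj = float(objs[i])
                best_p = pts[i]
                ties = 0
            elif objs[i] < best_obj + 1e-12:
                ties += 1
            return
        for v in values:
            recurse(prefix + [float(v)], remaining - float(v))

    recurse([], 100.0)
    assert best_p is not None
    proportions = tuple(
        (iid, float(pct))
        for iid, pct in zip(label.ingredients_desc, best_p)
    )
    residual = max(0.0, 100.0 - float(best_p.sum()))
    theoretical = theoretical_composition(
        proportions, table, water_residual_pct=residual
    )
    return RecipeEstimate(
        proportions=proportions,
        theoretical=theoretical,
        precision=estimation_precision(theoretical, label.declared),
        objective_value=best_obj,
        converged=True,
        n_iterations=n_points,
        uniqueness_flag="under-determined" if ties else "unique",
        water_residual_pct=residual,
    )
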