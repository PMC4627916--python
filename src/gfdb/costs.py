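"""Cost normalisation and the GF vs gluten-containing cost-disparity analysis.

Costs are compared on a per-kilogram basis (package price divided by package
mass), because package sizes differ systematically between gluten-free and
conventional products. The disparity is reported both as a ratio
(``relative_pct`` = 100 x GF/GC) and as an excess over parity
(``excess_pct`` = relative_pct - 100); survey reports are ambiguous between
the two readings, so both are always emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .core import MatchedSet
    from .stats import TestResult


def cost_per_kg(price_eur: float, package_mass_g: float) -> float:
    """Normalise a package price to EUR per kilogram."""
    if price_eur <= 0:
        raise ValueError(f"price_eur must be positive, got {price_eur}")
    if package_mass_g <= 0:
        raise ValueError(f"package_mass_g must be positive, got {package_mass_g}")
    return price_eur * 1000.0 / package_mass_g


@dataclass(frozen=True)
class CostComparison:
    category: str
    n_gf: int
    n_gc: int
    mean_gf_eur_per_kg: float
    mean_gc_eur_per_kg: float
    sd_gf: float | None
    sd_gc: float | None
    relative_pct: float
    excess_pct: float
    test: "TestResult | None"

    def __post_init__(self) -> None:
        if self.mean_gf_eur_per_kg <= 0 or self.mean_gc_eur_per_kg <= 0:
            raise ValueError("mean costs must be positive")


def cost_disparity(matched: Sequence["MatchedSet"]) -> list[CostComparison]:
    """Per-category and overall cost comparison over matched 1 GF : 2 GC sets.

    The gluten-containing mean is taken over *both* counterparts of every
    set (budget and premium), which centres it between the two cost tiers.
    Categories with fewer than two sets are skipped (a t-test needs n >= 2
    per group).
    """
    from .stats import summarize, unpaired_t

    if not matched:
        raise ValueError("no matched sets supplied")
    by_cat: dict[str, list["MatchedSet"]] = {}
    for m in matched:
        by_cat.setdefault(m.gf.category, []).append(m)

    def one(category: str, sets: Sequence["MatchedSet"]) -> CostComparison | None:
        gf_costs = [m.gf.cost_eur_per_kg for m in sets]
        gc_costs = [m.budget_counterpart.cost_eur_per_kg for m in sets]
        gc_costs += [m.premium_counterpart.cost_eur_per_kg for m in sets]
        if len(gf_costs) < 2:
            return None
        s_gf = summarize(gf_costs)
        s_gc = summarize(gc_costs)
        rel = 100.0 * s_gf.mean / s_gc.mean
        test = unpaired_t(gf_costs, gc_costs, label=f"cost {category}")
        return CostComparison(
            category=category,
            n_gf=len(gf_costs),
            n_gc=len(gc_costs),
            mean_gf_eur_per_kg=s_gf.mean,
            mean_gc_eur_per_kg=s_gc.mean,
            sd_gf=s_gf.sd_sample,
            sd_gc=s_gc.sd_sample,
            relative_pct=rel,
            excess_pct=rel - 100.0,
            test=test,
        )

    out: list[CostComparison] = []
    overall = one("overall", list(matched))
    if overall is not None:
        out.append(overall)
    for category in sorted(by_cat):
        cmp_ = one(category, by_cat[category])
        if cmp_ is not None:
            out.append(cmp_)
    return out
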