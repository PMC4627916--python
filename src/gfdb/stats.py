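"""Group summaries, two-sample tests, Bonferroni correction, and post-hoc
power for the GF vs gluten-containing comparison design.

Two standard-deviation conventions coexist in survey reports: the sample
SD (n-1 denominator) in prose and the population SD (n denominator) in
summary tables. Both are computed and labelled; prose-style sample SD is
the default everywhere a single SD is reported. Pooled rows enter every
statistic with weight 2, which for integer weights is identical to
duplicating the underlying observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .database import ProductProfile
from .nutrients import NUTRIENT_FIELDS, InvariantError


@dataclass(frozen=True)
class GroupSummary:
    """Weighted location/scale summary of one group."""

    n: int  # effective count, sum of pooled weights
    mean: float
    sd_sample: float | None  # n-1 denominator; None when n == 1
    sd_population: float | None  # n denominator
    sem: float | None

    def __post_init__(self) -> None:
        if self.n >= 2:
            assert self.sd_sample is not None and self.sd_population is not None
            expected = self.sd_sample * math.sqrt((self.n - 1) / self.n)
            assert abs(self.sd_population - expected) <= 1e-9 * max(1.0, expected)


@dataclass(frozen=True)
class TestResult:
    """Unpaired t-test output; F = t^2 matches two-group one-way ANOVA."""

    label: str
    statistic_t: float
    statistic_F: float
    df: float
    p_raw: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        assert abs(self.statistic_F - self.statistic_t**2) <= 1e-9
        assert 0.0 <= self.p_raw <= 1.0
        if self.p_adjusted is not None:
            assert self.p_adjusted >= self.p_raw - 1e-12


@dataclass(frozen=True)
class ChiSquareResult:
    label: str
    chi2: float
    df: int
    p_raw: float
    p_adjusted: float | None = None


@dataclass(frozen=True)
class PowerResult:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    alpha: float
    effect_size_d: float
    power: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.power <= 1.0


def _expand(
    values: Sequence[float], weights: Sequence[int] | None
) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if weights is None:
        return v
    w = np.asarray(weights)
    if len(w) != len(v):
        raise InvariantError("values and weights differ in length")
    if np.any(w < 1) or np.any(w != w.astype(int)):
        raise InvariantError("weights must be positive integers")
    return np.repeat(v, w.astype(int))


def summarize(
    values: Sequence[float], weights: Sequence[int] | None = None
) -> GroupSummary:
    """Weighted mean and SDs under both denominator conventions."""
    x = _expand(values, weights)
    if len(x) == 0:
        raise InvariantError("cannot summarize an empty group")
    n = len(x)
    mean = float(x.mean())
    if n == 1:
        return GroupSummary(n=1, mean=mean, sd_sample=None, sd_population=None, sem=None)
    sd_s = float(x.std(ddof=1))
    return GroupSummary(
        n=n,
        mean=mean,
        sd_sample=sd_s,
        sd_population=float(x.std(ddof=0)),
        sem=sd_s / math.sqrt(n),
    )


def unpaired_t(
    a: Sequence[float],
    b: Sequence[float],
    *,
    weights_a: Sequence[int] | None = None,
    weights_b: Sequence[int] | None = None,
    variance: str = "pooled",
    label: str = "",
) -> TestResult:
    """Two-sided unpaired t-test (pooled-variance Student by default).

    ``variance="welch"`` switches to the unequal-variance form. Groups
    with zero variance and equal means degenerate to t = 0, p = 1.
    """
    xa, xb = _expand(a, weights_a), _expand(b, weights_b)
    if len(xa) < 2 or len(xb) < 2:
        raise InvariantError("each group needs effective n >= 2")
    if variance not in ("pooled", "welch"):
        raise ValueError(f"unknown variance mode {variance!r}")
    if xa.var(ddof=1) == 0.0 and xb.var(ddof=1) == 0.0:
        if xa.mean() == xb.mean():
            df = float(len(xa) + len(xb) - 2)
            return TestResult(label, 0.0, 0.0, df, 1.0)
        raise InvariantError("degenerate zero-variance groups with unequal means")
    res = sps.ttest_ind(xa, xb, equal_var=(variance == "pooled"))
    t = float(res.statistic)
    return TestResult(
        label=label,
        statistic_t=t,
        statistic_F=t * t,
        df=float(res.df),
        p_raw=float(res.pvalue),
    )


def chi_square(counts: Sequence[Sequence[float]], label: str = "") -> ChiSquareResult:
    """Pearson chi-square on a 2x2 tag-by-group table, no Yates correction."""
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise InvariantError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise InvariantError("zero marginal in contingency table")
    res = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(
        label=label, chi2=float(res.statistic), df=int(res.dof), p_raw=float(res.pvalue)
    )


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: min(1, p*m), order-preserving."""
    if m < len(p_values):
        raise InvariantError(
            f"family size m={m} smaller than number of p-values ({len(p_values)})"
        )
    return [min(1.0, p * m) for p in p_values]


@dataclass(frozen=True)
class Comparison:
    """One nutrient-by-category GF vs GC comparison, or a skip record."""

    nutrient: str
    category: str
    gf: GroupSummary | None
    gc: GroupSummary | None
    test: TestResult | None
    skipped_reason: str | None = None

    @property
    def significant(self) -> bool | None:
        if self.test is None or self.test.p_adjusted is None:
            return None
        return self.test.p_adjusted < 0.05


def _group_values(
    profiles: Sequence[ProductProfile], nutrient: str
) -> tuple[list[float], list[int]]:
    vals, weights = [], []
    for p in profiles:
        v = p.nutrients.get(nutrient)
        if v is not None:
            vals.append(v)
            weights.append(p.pooled_weight)
    return vals, weights


def compare_all(
    gf: Sequence[ProductProfile],
    gc: Sequence[ProductProfile],
    nutrients: Sequence[str] | None = None,
    *,
    by_category: bool = True,
    variance: str = "pooled",
) -> list[Comparison]:
    """Per-nutrient comparisons, overall and per category.

    The Bonferroni family for each nutrient is its seven per-category
    tests (m = 7); the overall test for a nutrient stands alone and keeps
    its raw p. Missing nutrient values drop out with reduced n; a category
    with effective n < 2 in either group is skipped with a reason.
    """
    nutrients = tuple(nutrients) if nutrients is not None else NUTRIENT_FIELDS
    categories = sorted({p.category for p in list(gf) + list(gc)})
    out: list[Comparison] = []
    for nutrient in nutrients:
        scoped: list[tuple[str, Sequence[ProductProfile], Sequence[ProductProfile]]]
        scoped = [("overall", gf, gc)]
        if by_category:
            scoped += [
                (
                    cat,
                    [p for p in gf if p.category == cat],
                    [p for p in gc if p.category == cat],
                )
                for cat in categories
            ]
        results: list[Comparison] = []
        for scope, gf_sub, gc_sub in scoped:
            va, wa = _group_values(gf_sub, nutrient)
            vb, wb = _group_values(gc_sub, nutrient)
            if sum(wa) < 2 or sum(wb) < 2:
                results.append(
                    Comparison(
                        nutrient,
                        scope,
                        summarize(va, wa) if va else None,
                        summarize(vb, wb) if vb else None,
                        None,
                        skipped_reason=f"effective n < 2 (gf={sum(wa)}, gc={sum(wb)})",
                    )
                )
                continue
            try:
                test = unpaired_t(
                    va,
                    vb,
                    weights_a=wa,
                    weights_b=wb,
                    variance=variance,
                    label=f"{nutrient} {scope}",
                )
            except InvariantError as exc:
                results.append(
                    Comparison(
                        nutrient, scope, summarize(va, wa), summarize(vb, wb),
                        None, skipped_reason=str(exc),
                    )
                )
                continue
            results.append(
                Comparison(nutrient, scope, summarize(va, wa), summarize(vb, wb), test)
            )
        # Bonferroni family: the per-category tests of this nutrient.
        per_cat = [c for c in results if c.category != "overall" and c.test is not None]
        if per_cat:
            m = max(7, len(per_cat))
            adj = bonferroni([c.test.p_raw for c in per_cat], m)  # type: ignore[union-attr]
            adjusted = {id(c): a for c, a in zip(per_cat, adj)}
        else:
            adjusted = {}
        for c in results:
            if c.test is None:
                out.append(c)
            elif c.category == "overall":
                out.append(
                    Comparison(
                        c.nutrient, c.category, c.gf, c.gc,
                        TestResult(
                            c.test.label, c.test.statistic_t, c.test.statistic_F,
                            c.test.df, c.test.p_raw, p_adjusted=c.test.p_raw,
                        ),
                    )
                )
            else:
                out.append(
                    Comparison(
                        c.nutrient, c.category, c.gf, c.gc,
                        TestResult(
                            c.test.label, c.test.statistic_t, c.test.statistic_F,
                            c.test.df, c.test.p_raw, p_adjusted=adjusted[id(c)],
                        ),
                    )
                )
    return out


def power_two_means(
    mean1: float,
    mean2: float,
    sd1: float,
    sd2: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
) -> PowerResult:
    """Post-hoc power of a two-sided pooled-variance t-test.

    Uses the noncentral-t distribution with noncentrality
    delta = d * sqrt(n1*n2/(n1+n2)), where d is Cohen's d on the pooled
    SD. Equal means give power = alpha exactly.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise InvariantError("SDs must be > 0")
    if n1 < 2 or n2 < 2:
        raise InvariantError("need n >= 2 per group")
    if not 0 < alpha < 1:
        raise InvariantError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    sd_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    d = (mean1 - mean2) / sd_pooled
    delta = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = float(
        1.0 - sps.nct.cdf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta)
    )
    return PowerResult(
        mean1=mean1, mean2=mean2, sd1=sd1, sd2=sd2, n1=n1, n2=n2,
        alpha=alpha, effect_size_d=d, power=min(1.0, max(0.0, power)),
    )
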