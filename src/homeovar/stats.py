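"""Rank-based and categorical tests used in the expression-response analysis.

All comparisons in the analysis are between distributions of per-GO-term
coefficients of variation (or of per-GO mean expression), for which
rank-based tests are appropriate: CV distributions are right-skewed and
heavy-tailed, and only stochastic ordering is of interest.

The implementations delegate to scipy (Kruskal-Wallis H with midrank tie
correction, Mann-Whitney/Wilcoxon rank-sum with exact small-sample
p-values, Pearson chi-square); the test suite checks them against
independent brute-force enumeration oracles on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: Significance-star mapping used on the CV comparison figures:
#: * P<=0.05, ** P<=0.01, *** P<=0.001, **** P<=0.0001.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p_value: float) -> str:
    if not 0.0 <= p_value <= 1.0:
        raise ValidationError(f"p-value outside [0, 1]: {p_value}")
    for level, stars in STAR_LEVELS:
        if p_value <= level:
            return stars
    return "ns"


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome with its significance label."""

    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    adjustment: str = "none"
    direction: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean.

    Requires at least two values and a strictly positive mean; scale
    invariant under multiplication by any positive constant.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("CV requires at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError("CV requires a strictly positive mean")
    return float(arr.std(ddof=1) / mean)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    Midranks with the standard tie-correction factor; p-value from the
    chi-square approximation with k-1 degrees of freedom. If every pooled
    value is identical the test is degenerate and reported as H=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("Kruskal-Wallis: empty group")
    pooled = np.concatenate(groups)
    sizes = tuple(int(g.size) for g in groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, sizes)
    stat, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(stat), float(min(p, 1.0)), sizes)


def rank_sum_test(x, y, *, exact_max_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test of x vs y.

    Exact p-value when the combined sample size is at most
    ``exact_max_n`` and the pooled data are tie-free; otherwise the
    normal approximation with midrank tie correction (no continuity
    correction). The statistic is U for the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test: empty group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= exact_max_n and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        if np.all(pooled == pooled[0]):
            # degenerate: all values identical, no evidence either way
            return TestResult(
                "wilcoxon_asymptotic", float(x.size * y.size / 2), 1.0,
                (int(x.size), int(y.size)),
            )
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
    direction = None
    mu = x.size * y.size / 2
    if res.statistic > mu:
        direction = "x > y"
    elif res.statistic < mu:
        direction = "x < y"
    return TestResult(
        f"wilcoxon_{method}", float(res.statistic), float(min(res.pvalue, 1.0)),
        (int(x.size), int(y.size)), direction=direction,
    )


def pairwise_wilcoxon(
    reference,
    other_groups: Mapping[str, Sequence[float]],
    *,
    adjust: str = "none",
    exact_max_n: int = 20,
) -> dict[str, TestResult]:
    """Two-sided rank-sum test of each group against a shared reference.

    Used for the per-dosage-group CV comparisons against the balanced
    2:2 group. ``adjust="bh"`` applies Benjamini-Hochberg across the
    comparisons (the default reports raw p-values, matching per-group
    starring of the comparisons).
    """
    if adjust not in ("none", "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    raw: dict[str, TestResult] = {
        name: rank_sum_test(values, reference, exact_max_n=exact_max_n)
        for name, values in other_groups.items()
    }
    if adjust == "none" or not raw:
        return raw
    from statsmodels.stats.multitest import multipletests

    names = list(raw)
    _, p_adj, _, _ = multipletests(
        [raw[n].p_value for n in names], method="fdr_bh"
    )
    return {
        name: TestResult(
            raw[name].test_name, raw[name].statistic, float(p),
            raw[name].group_sizes, adjustment="bh",
            direction=raw[name].direction,
        )
        for name, p in zip(names, p_adj)
    }


def proportion_chisq(table, *, correction: bool = False) -> TestResult:
    """Pearson chi-square test on a 2x2 contingency table.

    No Yates continuity correction by default (expected counts in the
    class-proportion check are large). Zero row or column margins are a
    validation error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("chi-square: expected a 2x2 table")
    if (arr < 0).any():
        raise ValidationError("chi-square: negative counts")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ValidationError("chi-square: zero margin")
    res = sps.chi2_contingency(arr, correction=correction)
    sizes = tuple(int(n) for n in arr.sum(axis=1))
    return TestResult(
        "chi_square", float(res.statistic), float(min(res.pvalue, 1.0)), sizes
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def results_frame(results: Mapping[str, TestResult]):
    """Tabulate named test results for TSV output."""
    import pandas as pd

    rows = []
    for name, r in results.items():
        rows.append(
            (name, r.test_name, len(r.group_sizes), *_pad_sizes(r.group_sizes),
             r.statistic, r.p_value, r.adjustment, r.stars,
             "" if r.direction is None else r.direction)
        )
    return pd.DataFrame(
        rows,
        columns=["comparison", "test", "k", "n1", "n2", "statistic", "p",
                 "adjustment", "stars", "direction"],
    )


def _pad_sizes(sizes: tuple[int, ...]) -> tuple[int, int]:
    if len(sizes) >= 2:
        return sizes[0], sizes[1]
    return sizes[0], 0
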