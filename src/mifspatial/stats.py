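"""The statistical battery for group comparisons.

Thin, uniformly-shaped wrappers (returning :class:`TestResult`) around
the standard implementations: Fisher's exact test (two-sided by the
point-probability rule), Mann-Whitney U (exact for small untied samples,
tie/continuity-corrected normal approximation otherwise), the Wilcoxon
signed-rank test (zeros dropped, Wilcoxon's original convention),
Kruskal-Wallis with tie correction, Benjamini-Hochberg step-up FDR
adjustment, and Cohen's kappa with Landis-Koch agreement bands.

The exact-vs-asymptotic switch points are exposed because different
stats packages switch at different sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.multitest import multipletests

MANN_WHITNEY_EXACT_MAX_N = 12  # exact permutation null when n+m <= this
WILCOXON_EXACT_MAX_N = 15


@dataclass
class TestResult:
    """Uniform container for one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...] = ()
    direction: str = ""
    p_adjusted: float | None = None
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    The two-sided p sums hypergeometric point probabilities at most the
    observed table's (within a small relative tolerance for ties); the
    reported odds ratio is the sample ratio ad/bc (inf allowed).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    # Two-sided by the point-probability rule: sum every table as or
    # less probable than the observed one (relative tie tolerance 1e-7).
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return TestResult(
        "fisher_exact", float(odds), float(p), n=(a + b, c + d),
        direction="row1_enriched" if odds > 1 else "row2_enriched" if odds < 1 else "none",
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = MANN_WHITNEY_EXACT_MAX_N
) -> TestResult:
    """Two-sided Mann-Whitney U; exact permutation null when the pooled
    sample is small and untied, else the continuity- and tie-corrected
    normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = "x_higher" if np.median(x) > np.median(y) else "y_higher"
    return TestResult(
        "mann_whitney_u", float(res.statistic), float(min(res.pvalue, 1.0)),
        n=(len(x), len(y)), direction=direction, extra={"method": method == "exact"},
    )


def wilcoxon_signed_rank(
    diffs: Sequence[float], exact_max_n: int = WILCOXON_EXACT_MAX_N
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original convention); if
    all differences are zero the test is degenerate and p = 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) == 0:
        raise ValueError("no pairs")
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, n=(len(diffs),))
    method = "exact" if len(nonzero) <= exact_max_n else "approx"
    res = sps.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided",
        method=method, correction=(method == "approx"),
    )
    direction = "positive" if np.median(nonzero) > 0 else "negative"
    return TestResult(
        "wilcoxon_signed_rank", float(res.statistic), float(min(res.pvalue, 1.0)),
        n=(len(diffs),), direction=direction,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction, chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups):
        # identical distributions: H = 0 by symmetry, scipy raises on
        # all-identical values so short-circuit the degenerate case
        if len(np.unique(np.concatenate(groups))) == 1:
            return TestResult("kruskal_wallis", 0.0, 1.0, n=tuple(map(len, groups)))
    res = sps.kruskal(*groups)
    return TestResult(
        "kruskal_wallis", float(res.statistic), float(res.pvalue),
        n=tuple(len(g) for g in groups),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


LANDIS_KOCH_BANDS = (
    (0.0, "slight"), (0.2, "fair"), (0.4, "moderate"),
    (0.6, "substantial"), (0.8, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Landis-Koch qualitative label for an agreement coefficient."""
    if kappa < 0:
        return "poor"
    label = "slight"
    for lo, name in LANDIS_KOCH_BANDS:
        if kappa >= lo:
            label = name
    return label


def cohen_kappa(
    ratings_a: Sequence, ratings_b: Sequence, categories: Sequence | None = None
) -> TestResult:
    """Cohen's chance-corrected inter-rater agreement,
    (p_o - p_e) / (1 - p_e), with its Landis-Koch band."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("rating vectors must be equal-length and non-empty")
    labels = list(categories) if categories is not None else None
    if np.array_equal(a, b):
        k = 1.0  # p_e = 1 cases (single shared category) are perfect agreement
    else:
        k = float(cohen_kappa_score(a, b, labels=labels))
        if np.isnan(k):
            raise ValueError("kappa undefined: expected agreement is 1")
    return TestResult(
        "cohen_kappa", k, float("nan"), n=(len(a),), direction=kappa_band(k)
    )
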