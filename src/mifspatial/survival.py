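"""Kaplan-Meier estimation, log-rank testing and optimal-cutpoint
dichotomization of continuous biomarkers against progression-free
survival.

The cutpoint search follows the "significance" criterion of
cutpoint-optimization tools: scan the midpoints between consecutive
distinct biomarker values, keep splits leaving both arms at least
``max(3, min_group_frac * n)`` patients, and pick the split minimizing
the log-rank p.  The reported p is *unadjusted* for the optimization;
scanning cutpoints inflates the type-I error, which this package
measures (see the null-calibration tests) rather than corrects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from .stats import TestResult

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step
    function: S(0) = 1, steps down at event times only."""

    times: np.ndarray  # step locations, starting at 0
    survival: np.ndarray  # S(t) just after each step
    median: float = float("nan")

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if t[0] != 0.0:
        t = np.insert(t, 0, 0.0)
        s = np.insert(s, 0, 1.0)
    med = kmf.median_survival_time_
    return KMCurve(t, s, float(med))


def logrank_chi2(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> float:
    """Two-group log-rank chi-square via the aggregated risk-set
    (observed minus expected over event times) formula."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)  # True = group B
    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Standard two-group log-rank test (1 df chi-square)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        warnings.warn("no events in either group; log-rank p = 1")
        return TestResult("logrank", 0.0, 1.0, n=(len(ta), len(tb)))
    chi2 = logrank_chi2(
        np.concatenate([ta, tb]),
        np.concatenate([ea, eb]),
        np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)]),
    )
    p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return TestResult("logrank", chi2, p, n=(len(ta), len(tb)))


def km_points_frame(result: "CutoffResult", biomarker: str):
    """Tidy (biomarker, arm, time, survival) rows of both arms' KM
    curves, for plotting outside the package."""
    import pandas as pd

    rows = []
    for arm, curve in (("low", result.curve_low), ("high", result.curve_high)):
        for t, s in zip(curve.times, curve.survival):
            rows.append({
                "biomarker": biomarker, "arm": arm,
                "time_months": float(t), "survival": float(s),
            })
    return pd.DataFrame(rows)


@dataclass
class CutoffResult:
    """Optimal biomarker cutpoint against survival."""

    cutoff: float
    n_low: int
    n_high: int
    chi2: float
    p_value: float
    direction: str  # which arm has longer median survival
    median_low: float
    median_high: float
    curve_low: KMCurve
    curve_high: KMCurve
    candidates_scanned: int = 0


def optimal_cutoff(
    biomarker, times, events, min_group_frac: float = 0.1
) -> CutoffResult:
    """Minimum-log-rank-p dichotomization of a continuous biomarker.

    Candidates are midpoints between consecutive sorted distinct
    biomarker values; splits leaving either arm below
    ``max(3, min_group_frac * n)`` are discarded; ties on p break toward
    the more balanced split.  The returned p is unadjusted for the scan.
    """
    x = np.asarray(biomarker, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 evaluable patients")
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("biomarker has a single value; no cutpoint exists")
    min_arm = max(3, int(np.ceil(min_group_frac * n)))
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = None  # (p, imbalance, cutoff, chi2, high_mask)
    scanned = 0
    for c in candidates:
        high = x > c
        n_high = int(high.sum())
        if n_high < min_arm or n - n_high < min_arm:
            continue
        scanned += 1
        chi2 = logrank_chi2(t, e, high)
        p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
        key = (p, abs(n - 2 * n_high))
        if best is None or key < best[0]:
            best = (key, float(c), chi2, high)
    if best is None:
        raise ValueError("no candidate cutpoint satisfies the arm-size guard")
    (p, _), cutoff, chi2, high = best
    logger.warning(
        "optimal_cutoff scanned %d candidate splits; the reported p (%.4g) "
        "is unadjusted for cutpoint optimization and is anti-conservative",
        scanned, p,
    )
    low_curve = km_curve(t[~high], e[~high])
    high_curve = km_curve(t[high], e[high])
    if np.isnan(high_curve.median) and np.isnan(low_curve.median):
        direction = "indeterminate"
    elif np.isnan(high_curve.median) or high_curve.median > low_curve.median:
        direction = "high_longer_pfs"
    elif np.isnan(low_curve.median) or low_curve.median > high_curve.median:
        direction = "low_longer_pfs"
    else:
        direction = "equal"
    return CutoffResult(
        cutoff=cutoff,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        chi2=chi2,
        p_value=p,
        direction=direction,
        median_low=low_curve.median,
        median_high=high_curve.median,
        curve_low=low_curve,
        curve_high=high_curve,
        candidates_scanned=scanned,
    )
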