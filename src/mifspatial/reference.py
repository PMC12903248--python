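"""Published summary counts from the motivating 45-patient metastatic
melanoma immune-checkpoint-blockade cohort.

The patient-level cell data behind that study are not publicly
deposited, but several of its printed statistics derive from small
contingency tables and count/percentage pairs that can be recomputed
exactly.  This module freezes those counts and recomputes the derived
statistics through the package's own routines, serving as fixed-input
regression checks of the statistical battery.
"""

from __future__ import annotations

from .stats import fisher_exact_2x2, TestResult

# TIL spatial pattern vs response: patients showing any lymphocyte-
# excluded pattern (TIL patterns 0-2) versus inflamed/infiltrative,
# among 23 responders (16 excluded) and 22 non-responders (20 excluded).
TIL_EXCLUSION_TABLE = ((16, 7), (20, 2))

# Metabolic zonation vs response: 12/23 responders and 11/22
# non-responders showed a zonal marker gradient.
ZONATION_RESPONSE_TABLE = ((12, 11), (11, 11))

# Printed count/percentage pairs (count, denominator, printed percent).
COUNT_PERCENTAGES = {
    "peritheliomatous_growth": (13, 45, 29),
    "glut1_positive_cases": (28, 37, 76),
    "glut3_tcell_dominant_cases": (20, 21, 95),
    "ca9_positive_cases": (13, 41, 32),
    "zonal_cases": (23, 45, 51),
}


def til_exclusion_test() -> TestResult:
    """Fisher's exact test of lymphocyte-excluded TIL patterns (0-2)
    versus response."""
    (a, b), (c, d) = TIL_EXCLUSION_TABLE
    return fisher_exact_2x2(a, b, c, d)


def zonation_response_test() -> TestResult:
    """Fisher's exact test of metabolic zonation versus response."""
    (a, b), (c, d) = ZONATION_RESPONSE_TABLE
    return fisher_exact_2x2(a, b, c, d)


def recompute_percentages() -> dict[str, float]:
    """Percentages recomputed from the frozen counts (not the printed
    values), rounded to whole percent as printed."""
    return {
        name: round(100.0 * k / n)
        for name, (k, n, _printed) in COUNT_PERCENTAGES.items()
    }
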