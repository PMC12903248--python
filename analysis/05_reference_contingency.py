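"""Recompute the statistics derivable from the published cohort's
printed counts: the Fisher tests on the TIL-exclusion and
metabolic-zonation contingency tables and the count/percentage pairs.
Writes results/reference_stats.json.
"""

import json
from pathlib import Path

from mifspatial.reference import (
    COUNT_PERCENTAGES,
    recompute_percentages,
    til_exclusion_test,
    zonation_response_test,
)

OUT = Path("results")


def main() -> None:
    til = til_exclusion_test()
    zon = zonation_response_test()
    pct = recompute_percentages()
    payload = {
        "til_exclusion_fisher": {
            "p_value": round(til.p_value, 4), "odds_ratio": til.statistic,
        },
        "zonation_response_fisher": {
            "p_value": round(zon.p_value, 4), "odds_ratio": zon.statistic,
        },
        "percentages": {
            name: {"count": k, "denominator": n, "percent": pct[name]}
            for name, (k, n, _p) in COUNT_PERCENTAGES.items()
        },
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "reference_stats.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
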