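"""Cohort statistics on the simulated cohort: responder vs
non-responder Mann-Whitney per metric with BH control per family,
paired Wilcoxon on GLUT1+/GLUT1- region T-cell proportions, site-wise
Kruskal-Wallis, and the categorical Fisher tests.  Writes
results/comparisons.csv and prints the discoveries.

Requires analysis/01_simulate_cohort.py to have run.
"""

from pathlib import Path

import pandas as pd

from mifspatial.cell_io import PanelConfig, read_cell_table, read_cohort_manifest
from mifspatial.pipeline import RunConfig, compare_groups, run_sample

IN = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    cfg = RunConfig(panel=PanelConfig())
    metas = read_cohort_manifest(IN / "manifest.csv")
    metrics = [
        run_sample(meta, read_cell_table(IN / f"{meta.sample_id}.csv", cfg.panel), cfg.panel)
        for meta in metas
    ]
    comparisons = compare_groups(metrics, metas, cfg)
    OUT.mkdir(exist_ok=True)
    comparisons.to_csv(OUT / "comparisons.csv", index=False)
    hits = comparisons[comparisons["p_adjusted"] < 0.05]
    with pd.option_context("display.width", 160):
        print(f"{len(comparisons)} comparisons; "
              f"{len(hits)} significant after BH control:")
        print(hits[["family", "metric", "statistic", "p_value",
                    "p_adjusted", "direction"]].to_string(index=False))


if __name__ == "__main__":
    main()
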