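"""Optimal-cutpoint survival analysis on the simulated cohort: for each
spatial biomarker (mean distances and within-20-um proportions of
T-cell subsets to GLUT1+ melanoma), find the minimum-log-rank-p split
and report the Kaplan-Meier arm medians.  Writes results/survival.csv.

The reported p-values are unadjusted for the cutpoint scan and thus
anti-conservative; the null rejection rate of the scan is quantified by
scripts/acceptance.py.

Requires analysis/01_simulate_cohort.py to have run.
"""

from pathlib import Path

import pandas as pd

from mifspatial.cell_io import PanelConfig, read_cell_table, read_cohort_manifest
from mifspatial.pipeline import RunConfig, run_sample, run_survival

IN = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    cfg = RunConfig(panel=PanelConfig())
    metas = read_cohort_manifest(IN / "manifest.csv")
    metrics = [
        run_sample(meta, read_cell_table(IN / f"{meta.sample_id}.csv", cfg.panel), cfg.panel)
        for meta in metas
    ]
    km_points: list = []
    surv = run_survival(metrics, metas, cfg, km_points=km_points)
    OUT.mkdir(exist_ok=True)
    surv.to_csv(OUT / "survival.csv", index=False)
    if km_points:
        pd.concat(km_points, ignore_index=True).to_csv(
            OUT / "km_curves.csv", index=False
        )
    with pd.option_context("display.width", 160):
        print(surv.to_string(index=False))


if __name__ == "__main__":
    main()
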