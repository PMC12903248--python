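"""Per-sample processing of the simulated cohort: phenotyping, QC,
compartments, GLUT1 regions, zonation, TIL pattern and the proximity
metric battery.  Writes results/qc.csv and results/metrics.csv.

Requires analysis/01_simulate_cohort.py to have run.
"""

from pathlib import Path

from mifspatial.cell_io import PanelConfig, read_cell_table, read_cohort_manifest
from mifspatial.pipeline import run_sample, write_outputs

IN = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    panel = PanelConfig()
    metas = read_cohort_manifest(IN / "manifest.csv")
    metrics = []
    for meta in metas:
        table = read_cell_table(IN / f"{meta.sample_id}.csv", panel)
        metrics.append(run_sample(meta, table, panel))
    write_outputs(OUT, metrics)
    n_spatial = sum(m.qc.eligible_spatial for m in metrics)
    n_zonal = sum(
        1 for m in metrics if m.zonation is not None
        and m.zonation.defined and m.zonation.is_zonal
    )
    print(f"{len(metrics)} samples processed; {n_spatial} spatial-eligible; "
          f"{n_zonal} called zonal")
    print(f"wrote {OUT / 'qc.csv'} and {OUT / 'metrics.csv'}")


if __name__ == "__main__":
    main()
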