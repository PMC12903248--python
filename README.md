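# mifspatial

Spatial metabolic–immune profiling of multiplex-immunofluorescence (mIF)
cell tables from tumor biopsies.

Checkpoint-inhibitor response in metastatic melanoma depends not only on
how many T-cells a tumor contains but on *where* they sit relative to
metabolically reprogrammed (glycolytic / hypoxic) tumor regions.
`mifspatial` quantifies that geometry from the standard output of mIF
image analysis — one CSV row per segmented cell with µm coordinates and
marker intensities (SOX10, CD3, CD31, GLUT1, GLUT3, CA9, HIF1α) — and
relates it to immunotherapy outcome:

- **Phenotyping & QC** — threshold positivity calls, lineage assignment
  (SOX10⁺ melanoma, CD3⁺ T-cell, CD31⁺ endothelium), co-expression
  subsets such as CD3⁺GLUT3⁺GLUT1⁻, and sample-level inclusion rules
  (≥ 50 immune and ≥ 100 melanoma cells for spatial analysis).
- **Region stratification** — a density grid partitions tissue into
  tumor / peritumor compartments and segments tumor into GLUT1⁺ vs
  GLUT1⁻ regions from the kernel-smoothed GLUT1⁺ melanoma fraction.
- **Proximity statistics** — for query subset *Q* (T-cells) and target
  subset *T* (melanoma or vessels), the nearest-neighbor distances
  d<sub>i</sub> = min<sub>j∈T</sub> ‖x<sub>i</sub> − x<sub>j</sub>‖ give
  the mean distance and the proportion of *Q* within 20 µm of *T*,
  P̂ = #{i : d<sub>i</sub> ≤ 20 µm}/|Q|.
- **Metabolic zonation** — the GLUT1⁺ fraction of melanoma per
  distance-to-vessel decile; a sample is *zonal* when the Spearman trend
  is ≥ 0.7 with a dynamic range ≥ 0.10 (positivity rising away from
  vessels).
- **TIL pattern** — a rule cascade calls the lymphocyte distribution:
  0 absent, 1 peritumoral exclusion, 2 perivascular exclusion,
  3 inflamed/infiltrative.
- **Statistics** — Fisher exact (two-sided point-probability rule),
  Mann–Whitney U, Wilcoxon signed-rank, Kruskal–Wallis,
  Benjamini–Hochberg FDR control per analysis family, Cohen's κ.
- **Survival** — Kaplan–Meier curves, log-rank tests, and
  minimum-log-rank-p optimal cutpoints dichotomizing each spatial
  biomarker against progression-free survival (the scan's type-I-error
  inflation is measured, not hidden).
- **Synthetic ground truth** — a generator of vessel-anchored tumor
  nests with logistic distance-to-vessel GLUT positivity
  p(d) = 1/(1 + e^{−(d−d₀)/s}), independent-thinning T-cell exclusion
  (retention ρ in GLUT1-high neighborhoods), the four TIL patterns, and
  exponential PFS with log-hazard coupled to the true within-20 µm
  proximity — so every pipeline stage is testable against known truth.

## Worked example

```python
from mifspatial import PanelConfig, SimulationConfig, simulate_sample, run_sample

panel = PanelConfig()
meta, cells, truth = simulate_sample(SimulationConfig(seed=11), "EX01")
m = run_sample(meta, cells, panel)

print(f"sample {meta.sample_id}: {m.qc.n_melanoma} melanoma, "
      f"{m.qc.n_immune} T-cells, spatial-eligible={m.qc.eligible_spatial}")
print(f"GLUT1+ melanoma fraction: {m.values['melanoma_GLUT1_fraction']:.3f}")
print(f"mean NN distance CD3 -> GLUT1+ melanoma: "
      f"{m.values['mean_dist__CD3__to__melanoma_GLUT1']:.1f} um")
print(f"proportion of CD3 within 20 um of GLUT1+ melanoma: "
      f"{m.values['prop_within__CD3__to__melanoma_GLUT1']:.3f}")
print(f"T-cell share in GLUT1+ vs GLUT1- regions: "
      f"{m.values['tcell_prop_glut1_pos_region']:.3f} vs "
      f"{m.values['tcell_prop_glut1_neg_region']:.3f}")
print(f"zonation: trend={m.zonation.trend:.2f}, "
      f"range={m.zonation.fraction_range:.2f}, zonal={m.zonation.is_zonal}")
print(f"TIL pattern: {m.til_pattern.pattern} "
      f"(intratumoral share {m.til_pattern.intratumoral_share:.2f})")
```

```text
sample EX01: 2642 melanoma, 1443 T-cells, spatial-eligible=True
GLUT1+ melanoma fraction: 0.445
mean NN distance CD3 -> GLUT1+ melanoma: 138.8 um
proportion of CD3 within 20 um of GLUT1+ melanoma: 0.179
T-cell share in GLUT1+ vs GLUT1- regions: 0.183 vs 0.208
zonation: trend=1.00, range=0.91, zonal=True
TIL pattern: 3 (intratumoral share 0.48)
```

Reading this: 44.5% of tumor cells are glycolytic (GLUT1⁺); the average
T-cell sits 139 µm from its nearest GLUT1⁺ melanoma cell and 18% of
T-cells are in close (≤ 20 µm) contact with one; T-cells are mildly
depleted in GLUT1⁺ regions (0.183 vs 0.208 — this sample was generated
with retention ρ = 0.5); the GLUT1 gradient rises monotonically with
distance from vessels (zonal); and lymphocytes infiltrate the tumor
(pattern 3).

## Analysis project

Numbered drivers under `analysis/` run the full study on a simulated
45-patient cohort (23 responder-like / 22 non-responder-like) and write
tables under `results/`:

1. `01_simulate_cohort.py` — cohort CSVs + manifest + ground truth
2. `02_sample_metrics.py` — per-sample QC and metric battery
3. `03_group_comparisons.py` — responder vs non-responder Mann–Whitney
   with BH families, paired region Wilcoxon, site Kruskal–Wallis,
   categorical Fisher tests
4. `04_survival_cutoffs.py` — optimal-cutpoint Kaplan–Meier splits
5. `05_reference_contingency.py` — statistics recomputable from the
   published cohort's printed counts

The same pipeline is exposed as a CLI
(`mifspatial simulate|run|compare|survival|all`).

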