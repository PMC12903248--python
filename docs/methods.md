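# Methods

## The measurement problem

Multiplex immunofluorescence image analysis yields, per tissue sample,
a table of segmented cells with centroid coordinates (µm) and one
fluorescence intensity per marker. The scientific quantities of
interest here are all *spatial relationships between phenotype subsets*:
how close T-cells sit to glycolytic (GLUT1⁺/GLUT3⁺) melanoma, whether
metabolic marker expression forms a vessel-anchored gradient
("zonation"), whether lymphocytes are excluded from glycolytic tumor
regions, and whether those geometries predict progression-free survival
(PFS) under checkpoint blockade. Because the original patient-level
cell tables are not publicly deposited, the package pairs the analysis
pipeline with a generator of synthetic tumor microenvironments whose
ground truth is known exactly; all quantitative validation is against
that truth plus the handful of published statistics recomputable from
printed counts.

## Phenotyping

A cell is positive for a marker when `intensity >= threshold`
(inclusive: a fixed convention is needed and the boundary case must be
deterministic). Lineages resolve as SOX10⁺ → melanoma; CD3⁺SOX10⁻ →
T-cell; CD31⁺SOX10⁻CD3⁻ → endothelium; otherwise "other". SOX10⁺CD3⁺
double positives go to melanoma because SOX10 is the lineage anchor in
this panel; the conflict count is logged for audit. Intensity
thresholding stands in for a pathologist's partial-membranous-staining
criterion, which is not computable from a cell table; this is an
acknowledged approximation. Explicit positivity columns supplied in the
input win over recomputation (upstream tools may have used richer
criteria), with a logged warning.

Sample-level QC mirrors clinical practice: spatial analyses require at
least 50 immune and 100 melanoma cells; samples flagged
`dedifferentiated` (melanoma not reliably identifiable) are excluded
from tumor-dependent analyses; samples flagged `erythrocyte_only_glut1`
are excluded from GLUT1-specific analyses. Both flags are pathologist
inputs on the manifest, not computed.

## Region calling on a density grid

Pixel-level tissue classifiers cannot be reproduced from cell points,
so compartments and GLUT1 regions are called on a square grid (bin
50 µm, all parameters config-exposed):

- a bin is **tumor** if a melanoma cell lies within 50 µm of its
  center; **peritumor** bins lie within 200 µm of a tumor bin; cells
  inherit their bin's compartment;
- each tumor bin's GLUT1⁺ melanoma fraction is smoothed with a Gaussian
  kernel (σ = 25 µm) over tumor-bin centers, count-weighted so sparse
  bins borrow strength; bins at smoothed fraction ≥ 0.5 are **GLUT1⁺
  region**, the rest GLUT1⁻.

This is deterministic and idempotent. The paired per-sample exclusion
readout is the T-cell share of all cells in each region (primary, as a
proportion of cells) plus T-cells per mm² of region area (secondary).
Note a geometric subtlety quantified by the tests: with a zonal
gradient the GLUT1⁺ region is the nest rim, whose bins partially
overhang the nest edge; this inflates the rim's per-cell T-cell share
by up to ~+0.06 when there is no exclusion. The no-exclusion null of
the proportion difference is therefore checked on non-zonal (flat)
simulations, and exclusion recovery is demonstrated at retention
ρ ≤ 0.5 where the thinning signal dominates the rim bias.

**Zonation call.** Melanoma cells are binned by decile of
distance-to-nearest-CD31⁺-cell; the sample is zonal when the Spearman
correlation between decile index and GLUT1⁺ fraction is ≥ 0.7 *and* the
fraction range is ≥ 0.10. The published assessment was visual, so no
exact quantitative criterion exists to match; these thresholds separate
the generator's zonal and flat modes with ≥ 98% accuracy and are
config-exposed. Fewer than 10 melanoma cells → undefined.

**TIL pattern cascade** (all cutoffs config-exposed): density of CD3⁺
cells over the tumor+peritumor area < 5/mm² → 0 (absent); intratumoral
share of CD3⁺ cells < 20% → 1 (peritumoral exclusion); ≥ 70% of
intratumoral CD3⁺ within 30 µm of a CD31⁺ cell → 2 (perivascular
exclusion); else 3 (inflamed/infiltrative).

## Proximity metrics

All proximity metrics are directional: the mean/median nearest-neighbor
distance and the within-20 µm proportion are computed **over the query
population** (a T-cell subset) toward its nearest target (a melanoma
subset or vessels), matching the asymmetry of "proportion of T-cells
within 20 µm of a GLUT1⁺ melanoma cell". The 20 µm threshold is
boundary-inclusive. Nearest neighbors come from a k-d tree, with
equidistant targets tie-broken to the lowest target index so results
are deterministic and match a brute-force scan exactly; metrics are
invariant under translation and rotation of the coordinate frame.
Whether a published "average distance" averages over T-cells or over
proximity pairs is ambiguous; the mean over T-cells is primary here.

## Statistical battery

Wrapped implementations (scipy/statsmodels/sklearn) behind a uniform
result type: Mann–Whitney U (exact permutation null when the pooled
untied sample is ≤ 12, else tie- and continuity-corrected normal),
Wilcoxon signed-rank (zeros dropped — Wilcoxon's original convention —
exact for ≤ 15 nonzero pairs), Kruskal–Wallis with tie correction, and
Benjamini–Hochberg step-up adjustment applied within declared analysis
families (the family boundaries of the motivating analyses are not
fully enumerable, so families are configuration). Fisher's exact
two-sided p is computed in-package by the point-probability rule —
summing hypergeometric point probabilities ≤ the observed table's
(relative tie tolerance 1e-7) — and is verified against both scipy and
an exact integer-arithmetic enumeration on every 2×2 table with
N ≤ 60. Cohen's κ = (p_o − p_e)/(1 − p_e) carries its Landis–Koch band.

## Survival

Kaplan–Meier estimation uses lifelines; the log-rank statistic is the
standard aggregated risk-set (O − E)²/V form implemented in numpy (and
cross-checked against lifelines and a permutation null) because the
cutpoint scan calls it many times. The optimal cutpoint follows the
"significance" criterion of cutpoint-finder tools: candidate cutoffs
are midpoints between consecutive distinct biomarker values, splits
leaving an arm below max(3, 10% of n) are discarded, and the split
minimizing the log-rank p wins (ties → more balanced split). The
reported p is deliberately unadjusted for the scan, matching how such
results are usually presented; the resulting anti-conservatism is
*measured*: under a true null the scan rejects at ≈ 40% instead of 5%
(see `scripts/acceptance.py`, `cutpoint_null_rejection_pct`). Any
single reported cutpoint p-value must be read with that bias in mind.

## Synthetic tumor microenvironment

The generator encodes the biology the pipeline is meant to detect:

| parameter | default | meaning |
|---|---|---|
| extent | 2000 × 2000 µm | imaged field |
| n_vessels | 12 | straight CD31⁺ segments, length U(50, 200) µm, discretized every 10 µm |
| nest radius | U(180, 350) µm | one tumor-nest disc per vessel |
| melanoma_density | 1500 /mm² | homogeneous Poisson inside the nest union |
| tcell_density | 400 /mm² | base Poisson field before pattern shaping |
| d₀, s | 150 µm, 40 µm | logistic GLUT positivity p(d) = 1/(1+e^{−(d−d₀)/s}), d = distance to nearest vessel point |
| exclusion_rho | 0.5 | T-cell retention probability in GLUT1-high neighborhoods (local GLUT1⁺ melanoma fraction ≥ 0.5 within 50 µm) |
| outcome_beta | 2.0 | log-hazard decrease per unit of true within-20 µm CD3→GLUT1⁺ proportion |
| censoring | U(0, 14) months | gives roughly half the events observed |

GLUT3 and CA9 share the zonal geometry with effective midpoints 1.25·d₀
and 1.4·d₀, making them rarer on melanoma than GLUT1, as on tissue;
T-cell co-expression probabilities default to GLUT3 0.5 ≫ GLUT1 0.1
(real TILs are predominantly GLUT3⁺GLUT1⁻). Intensities are drawn from
two log-normal components ~7 log-SD apart so default thresholding
recovers the generating flags in > 99% of cells. Exclusion is
independent thinning, so the expected GLUT1⁺/GLUT1⁻ density ratio
equals ρ and recovery is testable in closed form. TIL patterns reshape
the base field: *absent* keeps a Poisson(5) remnant; *peritumoral*
keeps only the 200 µm band outside nests; *perivascular* keeps only
intratumoral cells within 30 µm of a vessel (keeping extratumoral cells
too would drive the intratumoral share below the cascade's 20% gate and
make the pattern definitionally unrecoverable); *infiltrative* keeps
everything.

PFS is exponential with log-hazard = log(log 2 / 6) − β·(true
within-20 µm proportion), censored uniformly. Cohorts derive
deterministic per-sample seeds from the master seed via
`SeedSequence.spawn`. Group labels in a simulated cohort must equal the
label implied by the 6-month PFS rule (the manifest validator enforces
consistency), so the outcome draw is rejection-resampled until the
realized PFS matches the intended group — the conditional outcome law
is the truncated exponential model. Responder-like samples default to
ρ = 0.8 (T-cells tolerated in glycolytic zones) vs ρ = 0.3 for
non-responder-like.

**What the generator does not emulate:** necrosis, tissue folds and
staining artifacts, irregular (non-disc) nest shapes, vessel curvature,
cell-size/morphology variation, segmentation errors, and spatial
correlation of marker noise. Passing recovery tests therefore shows the
pipeline detects these effects *when present in this idealized form*,
not that real tissue meets the model's assumptions.

## Problem sizes and numerical choices

Default densities give ~4–8×10³ cells per 2×2 mm sample — biopsy-scale
for an mIF field — and a 45-sample cohort processes end to end in about
half a minute on one CPU; replicate suites (50 per classifier mode) and
the 250-replicate null-calibration scans are sized to keep the full
test battery within a few minutes. Degenerate inputs are explicit:
empty samples yield all-outside compartments; GLUT1 segmentation
refuses samples with no melanoma in tumor bins (QC prevents them);
zonation is undefined below 10 melanoma cells or without vessels;
all-zero paired differences give p = 1 with a warning; a constant
biomarker or < 10 patients refuses cutpoint search. Exact-vs-asymptotic
switch points (12 for Mann–Whitney, 15 for Wilcoxon) follow common
practice and are arguments, since different stats packages switch at
different sizes.

## Known limitations

- Region calling is a density-grid surrogate for trained tissue
  classifiers; bin size and smoothing set its spatial resolution
  (boundary recovery is within ~one bin width).
- The per-cell region proportion carries a rim bias under zonal
  geometry (quantified above); the per-area density is reported
  alongside it.
- The zonation and TIL-pattern thresholds are calibrated to the
  generator's modes, not to pathologist consensus.
- Cutpoint-optimized survival p-values are anti-conservative by
  construction; the package measures but does not correct this.
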