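"""Cohort-level orchestration: per-sample processing, group statistics
and survival dichotomization, with CSV artifacts for every stage.

Stage order per sample: positivity calling -> phenotype assignment ->
QC -> compartment grid -> GLUT1 region segmentation (when eligible) ->
zonation -> TIL pattern -> the spatial metric battery.  QC failures mark
metrics ineligible; the run continues and the exclusion bookkeeping is
logged, because sample attrition is part of the method.

Benjamini-Hochberg families group the comparisons the way the analyses
naturally block: each named family is adjusted on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_io import CellTable, Cohort, PanelConfig, SampleMeta
from .phenotyping import QCReport, assign_phenotypes, call_positivity, qc_sample
from .regions import classify_compartments, segment_glut_regions
from .spatial import SampleMetrics, compute_sample_metrics, metrics_frame
from .stats import (
    TestResult,
    bh_adjust,
    fisher_exact_2x2,
    kruskal_wallis,
    mann_whitney_u,
    wilcoxon_signed_rank,
)
from .survival import km_points_frame, optimal_cutoff

logger = logging.getLogger(__name__)

# Default BH families: one per analysis block.
DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = {
    "proximity_distance": tuple(
        f"mean_dist__{q}__to__{t}"
        for q in ("CD3", "CD3_CA9", "CD3_HIF1A", "CD3_GLUT1", "CD3_GLUT3")
        for t in ("melanoma", "melanoma_GLUT1", "melanoma_GLUT3", "vessels")
    ),
    "proximity_within": tuple(
        f"prop_within__{q}__to__{t}"
        for q in ("CD3", "CD3_CA9", "CD3_HIF1A", "CD3_GLUT1", "CD3_GLUT3")
        for t in ("melanoma", "melanoma_GLUT1", "melanoma_GLUT3", "vessels")
    ),
    "tcell_fractions": tuple(
        f"tcell_{m}_fraction_{c}"
        for m in ("GLUT1", "GLUT3", "CA9", "HIF1A")
        for c in ("intratumoral", "peritumoral")
    ),
    "melanoma_fractions": tuple(
        f"melanoma_{m}_fraction" for m in ("GLUT1", "GLUT3", "CA9", "HIF1A")
    ),
}

DEFAULT_SURVIVAL_BIOMARKERS = (
    "mean_dist__CD3__to__melanoma_GLUT1",
    "mean_dist__CD3_CA9__to__melanoma_GLUT1",
    "mean_dist__CD3_GLUT1__to__melanoma_GLUT1",
    "prop_within__CD3__to__melanoma_GLUT1",
    "prop_within__CD3_CA9__to__melanoma_GLUT1",
    "prop_within__CD3_GLUT1__to__melanoma_GLUT1",
)


@dataclass
class RunConfig:
    """Cohort-run configuration."""

    panel: PanelConfig = field(default_factory=PanelConfig)
    bh_families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FAMILIES)
    )
    survival_biomarkers: tuple[str, ...] = DEFAULT_SURVIVAL_BIOMARKERS
    min_survival_n: int = 10
    seed: int = 0


def run_sample(
    meta: SampleMeta, table: CellTable, panel: PanelConfig
) -> SampleMetrics:
    """Process one sample end to end; deterministic."""
    table = call_positivity(table, panel)
    table = assign_phenotypes(table)
    qc = qc_sample(table, meta, panel)
    table, grid = classify_compartments(table, panel)
    if qc.eligible_glut1 and grid.melanoma_count.sum() > 0 and (grid.compartment == 1).any():
        table, grid = segment_glut_regions(table, grid, panel)
    metrics = compute_sample_metrics(table, grid, panel, meta, qc)
    logger.info(
        "sample %s: %d melanoma, %d immune, spatial=%s glut1=%s reasons=%s",
        meta.sample_id, qc.n_melanoma, qc.n_immune,
        qc.eligible_spatial, qc.eligible_glut1, "; ".join(qc.reasons) or "-",
    )
    return metrics


def run_cohort(cohort: Cohort, config: RunConfig) -> list[SampleMetrics]:
    return [run_sample(meta, table, config.panel) for meta, table in cohort.samples]


def _metric_by_group(
    metrics: list[SampleMetrics], metas: list[SampleMeta], name: str
) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for m, meta in zip(metrics, metas):
        v = m.values.get(name)
        if v is None or not m.eligible.get(name, False) or not np.isfinite(v):
            continue
        groups.setdefault(meta.response, []).append(v)
    return {k: np.asarray(v) for k, v in groups.items()}


def compare_groups(
    metrics: list[SampleMetrics],
    metas: list[SampleMeta],
    config: RunConfig,
) -> pd.DataFrame:
    """The cohort comparison battery.

    Mann-Whitney responder vs non-responder per metric, BH-adjusted
    within each declared family; paired Wilcoxon on GLUT1+ vs GLUT1-
    region T-cell proportions (overall and within each response group);
    Kruskal-Wallis across biopsy sites for the marker fractions.
    """
    rows: list[dict[str, object]] = []

    for family, names in config.bh_families.items():
        fam_rows = []
        for name in names:
            by_group = _metric_by_group(metrics, metas, name)
            x = by_group.get("responder", np.empty(0))
            y = by_group.get("nonresponder", np.empty(0))
            if len(x) < 2 or len(y) < 2:
                logger.info("skipping %s: group sizes %d/%d", name, len(x), len(y))
                continue
            res = mann_whitney_u(x, y)
            fam_rows.append({
                "family": family, "metric": name, "test": res.name,
                "statistic": res.statistic, "p_value": res.p_value,
                "n_responder": len(x), "n_nonresponder": len(y),
                "direction": res.direction,
            })
        if fam_rows:
            adj = bh_adjust([r["p_value"] for r in fam_rows])
            for r, pa in zip(fam_rows, adj):
                r["p_adjusted"] = float(pa)
            rows.extend(fam_rows)

    # Paired region comparison (GLUT1+ vs GLUT1- within the same sample).
    for label in (None, "responder", "nonresponder"):
        diffs = []
        for m, meta in zip(metrics, metas):
            if label is not None and meta.response != label:
                continue
            rp = m.region_proportions
            if rp is not None and rp.defined:
                diffs.append(rp.prop_pos - rp.prop_neg)
        if len(diffs) >= 5:
            res = wilcoxon_signed_rank(diffs)
            rows.append({
                "family": "region_paired",
                "metric": "tcell_prop_glut1_pos_minus_neg"
                          + (f"__{label}" if label else ""),
                "test": res.name, "statistic": res.statistic,
                "p_value": res.p_value, "p_adjusted": res.p_value,
                "n_responder": sum(1 for mm in metas if mm.response == "responder"),
                "n_nonresponder": sum(1 for mm in metas if mm.response == "nonresponder"),
                "direction": res.direction,
            })
        else:
            logger.info("region_paired %s skipped: %d evaluable pairs", label, len(diffs))

    # Site comparison (Kruskal-Wallis over biopsy sites).
    for name in config.bh_families.get("melanoma_fractions", ()):
        by_site: dict[str, list[float]] = {}
        for m, meta in zip(metrics, metas):
            v = m.values.get(name)
            if v is not None and m.eligible.get(name, False) and np.isfinite(v):
                by_site.setdefault(meta.site, []).append(v)
        groups = [g for g in by_site.values() if len(g) >= 2]
        if len(groups) >= 2:
            res = kruskal_wallis(groups)
            rows.append({
                "family": "site_comparison", "metric": name, "test": res.name,
                "statistic": res.statistic, "p_value": res.p_value,
                "p_adjusted": float("nan"),
                "n_responder": -1, "n_nonresponder": -1, "direction": "",
            })

    # Categorical: lymphocyte-excluded patterns (0-2) vs infiltrative,
    # and metabolic zonation, against response.
    def fisher_row(metric: str, flag) -> None:
        counts = {("responder", True): 0, ("responder", False): 0,
                  ("nonresponder", True): 0, ("nonresponder", False): 0}
        for m, meta in zip(metrics, metas):
            f = flag(m)
            if f is None:
                continue
            counts[(meta.response, f)] += 1
        a, b = counts[("responder", True)], counts[("responder", False)]
        c, d = counts[("nonresponder", True)], counts[("nonresponder", False)]
        if a + b == 0 or c + d == 0:
            return
        res = fisher_exact_2x2(a, b, c, d)
        rows.append({
            "family": "clinicopathologic", "metric": metric, "test": res.name,
            "statistic": res.statistic, "p_value": res.p_value,
            "p_adjusted": float("nan"),
            "n_responder": a + b, "n_nonresponder": c + d,
            "direction": res.direction,
        })

    fisher_row(
        "til_excluded_patterns_0_2",
        lambda m: (m.til_pattern.pattern <= 2) if m.til_pattern is not None else None,
    )
    fisher_row(
        "metabolic_zonation",
        lambda m: (m.zonation.is_zonal if (m.zonation is not None and m.zonation.defined
                                           and m.qc.eligible_glut1) else None),
    )

    df = pd.DataFrame(rows)
    # Adjust the clinicopathologic family jointly.
    if len(df):
        mask = df["family"] == "clinicopathologic"
        if mask.any():
            df.loc[mask, "p_adjusted"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    return df


def run_survival(
    metrics: list[SampleMetrics],
    metas: list[SampleMeta],
    config: RunConfig,
    km_points: list[pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Optimal-cutoff Kaplan-Meier split for each configured biomarker.

    Pass a list as ``km_points`` to additionally collect the tidy KM
    curve points of both arms per biomarker (for external plotting).
    """
    rows = []
    for name in config.survival_biomarkers:
        xs, ts, es = [], [], []
        for m, meta in zip(metrics, metas):
            v = m.values.get(name)
            if v is None or not m.eligible.get(name, False) or not np.isfinite(v):
                continue
            xs.append(v)
            ts.append(meta.pfs_months)
            es.append(meta.event)
        if len(xs) < config.min_survival_n:
            logger.info("survival %s skipped: %d evaluable patients", name, len(xs))
            continue
        try:
            res = optimal_cutoff(np.asarray(xs), np.asarray(ts), np.asarray(es))
        except ValueError as err:
            logger.info("survival %s skipped: %s", name, err)
            continue
        if km_points is not None:
            km_points.append(km_points_frame(res, name))
        rows.append({
            "biomarker": name, "cutoff": res.cutoff,
            "n_low": res.n_low, "n_high": res.n_high,
            "chi2": res.chi2, "p_value": res.p_value,
            "direction": res.direction,
            "median_low": res.median_low, "median_high": res.median_high,
        })
    return pd.DataFrame(rows)


def qc_frame(metrics: list[SampleMetrics]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample_id": m.qc.sample_id,
            "n_melanoma": m.qc.n_melanoma,
            "n_immune": m.qc.n_immune,
            "eligible_spatial": m.qc.eligible_spatial,
            "eligible_tumor_analysis": m.qc.eligible_tumor_analysis,
            "eligible_glut1": m.qc.eligible_glut1,
            "reasons": "; ".join(m.qc.reasons),
        }
        for m in metrics
    ])


def write_outputs(
    out_dir: str | Path,
    metrics: list[SampleMetrics],
    comparisons: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
    km_points: list[pd.DataFrame] | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc_frame(metrics).to_csv(out / "qc.csv", index=False)
    metrics_frame(metrics).to_csv(out / "metrics.csv", index=False)
    if comparisons is not None:
        comparisons.to_csv(out / "comparisons.csv", index=False)
    if survival is not None:
        survival.to_csv(out / "survival.csv", index=False)
    if km_points:
        pd.concat(km_points, ignore_index=True).to_csv(
            out / "km_curves.csv", index=False
        )
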