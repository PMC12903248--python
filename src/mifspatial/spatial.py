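"""Nearest-neighbor proximity metrics between phenotype point sets.

The directional convention throughout: metrics are computed over the
*query* population (typically a T-cell subset) toward its nearest
*target* cell (typically a melanoma subset or vessels).  "Proportion
within 20 um" is the fraction of query cells whose nearest target lies
at most the threshold away (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_io import CellTable, PanelConfig, SampleMeta
from .phenotyping import QCReport, marker_fraction, subset_mask
from .regions import (
    RegionGrid,
    RegionProportions,
    TilPatternCall,
    ZonationResult,
    call_metabolic_zonation,
    classify_til_pattern,
    region_tcell_proportion,
)

# The metric battery: T-cell subsets vs melanoma subsets and vessels.
QUERY_SUBSETS: dict[str, tuple[str, ...]] = {
    "CD3": (),
    "CD3_CA9": ("CA9",),
    "CD3_HIF1A": ("HIF1A",),
    "CD3_GLUT1": ("GLUT1",),
    "CD3_GLUT3": ("GLUT3",),
}
TARGET_SUBSETS: dict[str, tuple[str, tuple[str, ...]]] = {
    "melanoma": ("melanoma", ()),
    "melanoma_GLUT1": ("melanoma", ("GLUT1",)),
    "melanoma_GLUT3": ("melanoma", ("GLUT3",)),
    "melanoma_CA9": ("melanoma", ("CA9",)),
    "melanoma_HIF1A": ("melanoma", ("HIF1A",)),
    "vessels": ("endothelium", ()),
}
GLUT1_SPECIFIC_TOKENS = ("GLUT1", "glut1")


@dataclass
class ProximityResult:
    """Nearest-neighbor summary for one (query, target) pair."""

    query: str
    target: str
    n_query: int
    n_target: int
    threshold_um: float
    mean_nn_um: float = float("nan")
    median_nn_um: float = float("nan")
    proportion_within: float = float("nan")
    eligible: bool = True
    reason: str = ""


def nn_distances(
    query: np.ndarray, target: np.ndarray, return_index: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Euclidean distance from each query point to its nearest target.

    Equidistant targets tie-break to the lowest target index, so the
    result is deterministic and matches a brute-force argmin scan.
    """
    query = np.asarray(query, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(target) == 0:
        raise ValueError("empty target set")
    tree = cKDTree(target)
    d, idx = tree.query(query)
    if return_index:
        # Enforce lowest-index tie-break among exactly equidistant targets.
        for i in range(len(query)):
            cands = tree.query_ball_point(query[i], d[i] * (1 + 1e-12) + 1e-12)
            if len(cands) > 1:
                dd = np.linalg.norm(target[cands] - query[i], axis=1)
                exact = [c for c, x in zip(cands, dd) if x == d[i]]
                if exact:
                    idx[i] = min(exact)
        return d, idx
    return d


def proximity_summary(
    query: np.ndarray,
    target: np.ndarray,
    threshold_um: float = 20.0,
    query_name: str = "query",
    target_name: str = "target",
    eligible: bool = True,
    reason: str = "",
) -> ProximityResult:
    """Mean/median nearest-neighbor distance and the within-threshold
    proportion for a query set against a target set."""
    nq, nt = len(query), len(target)
    if not eligible or nq == 0 or nt == 0:
        if nq == 0 or nt == 0:
            reason = reason or f"empty point set (n_query={nq}, n_target={nt})"
        return ProximityResult(
            query_name, target_name, nq, nt, threshold_um,
            eligible=False, reason=reason,
        )
    d = nn_distances(query, target)
    return ProximityResult(
        query=query_name,
        target=target_name,
        n_query=nq,
        n_target=nt,
        threshold_um=threshold_um,
        mean_nn_um=float(np.mean(d)),
        median_nn_um=float(np.median(d)),
        proportion_within=float(np.mean(d <= threshold_um)),
    )


def proximity_pairs(
    query: np.ndarray, target: np.ndarray, threshold_um: float = 20.0
) -> list[tuple[int, int, float]]:
    """One (query_index, nearest_target_index, distance) per query cell
    whose nearest target lies within the threshold."""
    if len(query) == 0 or len(target) == 0:
        return []
    d, idx = nn_distances(query, target, return_index=True)
    return [
        (int(i), int(idx[i]), float(d[i]))
        for i in np.flatnonzero(d <= threshold_um)
    ]


@dataclass
class SampleMetrics:
    """All derived quantities for one sample."""

    sample_id: str
    qc: QCReport
    values: dict[str, float] = field(default_factory=dict)
    eligible: dict[str, bool] = field(default_factory=dict)
    proximity: dict[str, ProximityResult] = field(default_factory=dict)
    zonation: ZonationResult | None = None
    til_pattern: TilPatternCall | None = None
    region_proportions: RegionProportions | None = None

    def set(self, name: str, value: float, eligible: bool = True) -> None:
        self.values[name] = float(value)
        self.eligible[name] = bool(eligible)

    def eligible_values(self) -> dict[str, float]:
        return {
            k: v for k, v in self.values.items()
            if self.eligible.get(k, False) and np.isfinite(v)
        }

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {"sample_id": self.sample_id}
        for k, v in self.values.items():
            row[k] = v if self.eligible.get(k, False) else float("nan")
        return row


def _is_glut1_specific(name: str) -> bool:
    return any(tok in name for tok in GLUT1_SPECIFIC_TOKENS)


def compute_sample_metrics(
    table: CellTable,
    grid: RegionGrid,
    panel: PanelConfig,
    meta: SampleMeta,
    qc: QCReport,
) -> SampleMetrics:
    """The full per-sample metric battery.

    Requires phenotyping, compartments and (when GLUT1-eligible) region
    segmentation to have run.  Every metric carries its own eligibility:
    spatial metrics need the sample-level QC gate, GLUT1-specific
    metrics additionally need the GLUT1 eligibility flag.
    """
    sm = SampleMetrics(meta.sample_id, qc)
    df = table.cells
    thr = panel.proximity_threshold_um

    # Marker fractions on melanoma (tumor compartment) and on T-cells by
    # compartment.
    for m in ("GLUT1", "GLUT3", "CA9", "HIF1A"):
        ok = qc.eligible_tumor_analysis and (qc.eligible_glut1 or m != "GLUT1")
        frac = marker_fraction(table, "melanoma", m, "tumor")
        sm.set(f"melanoma_{m}_fraction", frac, ok and np.isfinite(frac))
        for comp in ("tumor", "peritumor"):
            tfrac = marker_fraction(table, "tcell", m, comp)
            name = f"tcell_{m}_fraction_{'intratumoral' if comp == 'tumor' else 'peritumoral'}"
            sm.set(name, tfrac, ok and np.isfinite(tfrac))

    # Proximity battery.
    spatial_ok = qc.eligible_spatial
    for qname, qmarkers in QUERY_SUBSETS.items():
        q_xy = table.points(subset_mask(table, "tcell", *qmarkers))
        for tname, (tpheno, tmarkers) in TARGET_SUBSETS.items():
            t_xy = table.points(subset_mask(table, tpheno, *tmarkers))
            key = f"{qname}__to__{tname}"
            ok = spatial_ok and (
                qc.eligible_glut1 or not _is_glut1_specific(key)
            )
            res = proximity_summary(
                q_xy, t_xy, thr, qname, tname,
                eligible=ok, reason="" if ok else "QC-ineligible",
            )
            sm.proximity[key] = res
            sm.set(f"mean_dist__{key}", res.mean_nn_um, res.eligible)
            sm.set(f"prop_within__{key}", res.proportion_within, res.eligible)

    # Melanoma classes to vessels (zonation geometry).
    vessel_xy = table.points(table.phenotype_mask("endothelium"))
    for tname, markers in (
        ("melanoma", ()), ("melanoma_GLUT1", ("GLUT1",)), ("melanoma_GLUT3", ("GLUT3",)),
    ):
        mel_xy = table.points(subset_mask(table, "melanoma", *markers))
        ok = qc.eligible_tumor_analysis and (
            qc.eligible_glut1 or not _is_glut1_specific(tname)
        )
        res = proximity_summary(
            mel_xy, vessel_xy, thr, tname, "vessels",
            eligible=ok, reason="" if ok else "QC-ineligible",
        )
        sm.set(f"mean_dist__{tname}__to__vessels", res.mean_nn_um, res.eligible)

    # Region-stratified T-cell proportions (paired GLUT1+ vs GLUT1-).
    if qc.eligible_glut1 and "region" in df.columns:
        rp = region_tcell_proportion(table, grid)
        sm.region_proportions = rp
        sm.set("tcell_prop_glut1_pos_region", rp.prop_pos, rp.defined)
        sm.set("tcell_prop_glut1_neg_region", rp.prop_neg, rp.defined)
        sm.set("tcell_density_glut1_pos_region", rp.density_pos_per_mm2, rp.defined)
        sm.set("tcell_density_glut1_neg_region", rp.density_neg_per_mm2, rp.defined)
    else:
        sm.region_proportions = RegionProportions(False, reason="GLUT1-ineligible")

    # Zonation and TIL pattern.
    zon = call_metabolic_zonation(table, panel)
    sm.zonation = zon
    sm.set("zonation_trend", zon.trend, zon.defined and qc.eligible_glut1)
    sm.set(
        "is_zonal", float(zon.is_zonal) if zon.defined else float("nan"),
        zon.defined and qc.eligible_glut1,
    )
    til = classify_til_pattern(table, grid, panel)
    sm.til_pattern = til
    sm.set("til_pattern", float(til.pattern), True)
    sm.set("tcell_overall_share", float(df["phenotype"].eq("tcell").mean()) if len(df) else float("nan"), len(df) > 0)
    return sm


def metrics_frame(metrics: list[SampleMetrics]) -> pd.DataFrame:
    """One row per sample; QC-ineligible metrics appear as NaN."""
    return pd.DataFrame([m.to_row() for m in metrics])
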